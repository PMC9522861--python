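# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that make results reproducible bit for bit.

## Study design and data model

The intended input is a protein-group LFQ matrix over a paired design:
hemisphere (L/R) crossed with an ordered set of timepoints (gestational weeks,
default 9/11/13), one specimen per timepoint — six samples in total. LFQ
intensities are non-negative on an arbitrary scale; zero encodes "not
detected", which conflates true absence with dropout below the instrument's
effective detection limit. All identification-level filtering (contaminant,
reverse-decoy and site-only flags) happens on read; any non-empty flag cell
counts as flagged, and the protein-group id is the leading accession of the
majority-protein field.

"Detected" is LFQ > 0 throughout. The core protein set (detected in all
samples) is the domain of every cross-timepoint analysis because it is the
largest submatrix with no missing values; everything outside it is handled by
the per-week laterality screens, which tolerate one-sided zeros by design.

## Differential expression between timepoints

L and R samples of a week are pooled as replicates of that week, i.e. the
tissue is treated as a whole and the laterality signal contributes to the
residual. This is deliberate: with one specimen per week there is no other
source of within-group replication. The cost is a conservatively inflated
residual variance for strongly lateralized proteins.

The model is a one-way layout on log2 intensities: per-protein week means,
pooled within-week variance s²_g on d_g = n − k df (3 for the 6-sample,
3-week design), and consecutive-week contrasts (later minus earlier, so
positive log2FC = rises with age) with unscaled variance v = 1/n_a + 1/n_b.

Variance moderation follows the hierarchical model s²_g ~ s₀²·F(d_g, d₀).
On z = log s²_g this gives E[z] and Var[z] in closed form through digamma and
trigamma functions; d₀ solves trigamma(d₀/2) = Var(e) − trigamma(d_g/2)
(e is z recentred by the d_g terms) by Brent's method on [1e−6, 1e6] with
xtol 1e−8, and s₀² follows from the mean equation. If the observed dispersion
does not exceed what d_g alone explains, d₀ = +∞ and every moderated variance
equals s₀². Note that with identical raw variances the estimated s₀² exceeds
the common value by exp(log(d_g/2) − digamma(d_g/2)) — the log-chi-square
skewness correction; this matches the reference R implementation of the same
moment equations, against which the package is tested. Zero variances are
excluded from the moment fit (log 0) but still shrunk; an all-zero input is
flagged degenerate and the t-statistic refuses downstream.

The moderated t has d_g + d₀ df (normal tail when d₀ = +∞). BH adjustment is
applied per week interval. Calls are strict: |log2FC| > log2(2) and
FDR < 0.05; a protein at the boundary is not significant. Reported DEP
fractions of the core set are rounded to two decimals of a percent.

## Per-week laterality screen

All quantities are computed on raw LFQ intensities (fold changes on the raw
scale are what the screen thresholds), per week, over proteins with L + R > 0:

* AI = (L − R)/(L + R), undefined only when both sides are zero.
* significance A on x = log2(L/R) of both-side-detected proteins: robust
  side-specific z from the 15.87/50/84.13 percentiles, p = ½·erfc(z/√2).
  The p is one-sided by construction (p = 0.5 at the median, uniform on
  (0, 0.5] under a matching null, so each tail flags ~5% at p < 0.05); no
  doubling is applied, matching the original outlier-test formulation. A
  degenerate side (zero interquantile width) yields p = 1 on that side with a
  logged warning; fewer than 20 finite ratios logs a low-power warning but
  still computes.
* Credibility floor: the 1st percentile (linear-interpolation convention,
  like all percentiles here) of (L + R)/2 over detected proteins at that
  week.

Classes partition the detected proteins: `aep_left`/`aep_right` (both sides
detected, fold > 2 strict, p < 0.05 strict), `unilateral_left`/
`unilateral_right` (exactly one side zero), `bilateral_ns` otherwise. An
asymmetric or unilateral call whose mean intensity falls below the floor is
re-classed `low_intensity`; symmetric proteins are never re-classed, so the
floor only suppresses positive calls, which is its purpose. Swapping the L
and R columns mirrors every class and negates AI exactly.

Shared asymmetry across weeks uses two rules: the full rule counts weeks with
an AEP class (threshold min_gws = 2, with the exactly-two decomposition per
week pair), and a relaxed screen requires raw fold change ≥ 1.5 (inclusive,
as a screening criterion) at *every* week with no significance requirement —
direction is recorded per week but not required consistent. The relaxed rule
considers only proteins detected on both sides at every week, keeping the
one-sided proteins in their own category.

## Temporal profile clustering

Trajectories are clustered against a fixed library of integer-step shapes:
all (2c+1)^(T−1) sequences starting at 0 with per-step change in [−c, c].
Defaults c = 2, m = 16 model profiles for T = 3. Selection is greedy max–min:
seed with the flat shape, repeatedly add the candidate maximizing the minimum
distance d = 1 − r (Pearson) to the selected set. Distances are rounded to 12
decimals before comparison so ties that are exact in real arithmetic (integer
shapes give rational correlations) break by enumeration index rather than by
floating-point noise; the procedure is fully deterministic.

Assignment transforms each series to differences from its own first timepoint
and picks the most correlated model shape. Conventions for the flat profile:
a constant series is assigned to it directly; for a non-constant series the
correlation with the flat shape is 0. Collinear shapes (e.g. 0,1,0 and 0,2,0)
are equivalent under correlation; ties break toward the lowest profile id.

Enrichment: for each protein the assignment is recomputed under all T!
orderings of its values (exact enumeration, refused above T! = 5,000), E_j is
the mean per-profile assignment mass, and p_j = P(X ≥ n_j) for
X ~ Binomial(N, E_j/N) — an inclusive upper tail, significant at p ≤ α
(default 0.05). The binomial is an approximation to the exact
Poisson-binomial null and is slightly conservative in the tail; expected
counts conserve ΣE_j = N exactly.

## Sample summaries

PCA treats proteins as observations and samples as variables, standardizing
columns (ddof 1) so the analysed matrix is the sample correlation matrix —
chosen because per-sample scores over a handful of samples are the quantity
of interest, and the correlation matrix removes the arbitrary per-sample
intensity scale. Per-sample scores are loadings scaled by the PC standard
deviation (the correlation of each sample with each PC); percent variances
sum to 100. Constant proteins are dropped with a logged warning; likewise
zero-variance samples yield NaN correlations rather than silent zeros.

## Synthetic data generator

Per protein: log2 baseline ~ N(25, 2²) (typical LFQ log2 scale), a temporal
trend shape on the log2 scale (defaults: 60% flat, 10% each monotone up/down
at 0.75/week and late up/down at 1.5 in the final interval), an optional
hemisphere effect (default 5% of proteins per week at +1.5 log2 units on one
side — chosen to mirror AEP rates of a few percent in paired brain tissue),
5% one-sided proteins (forced zero on one side at every week), and i.i.d.
N(0, 0.25²) log2 noise per sample. Realized intensities drop out with
probability logistic((m − log2 I)·k), defaults m = 20, k = 0.8, so
missingness concentrates at low abundance — the feature the credibility floor
exists to handle. Dropout acts on realized (noisy) intensities; unilateral
zeroing happens last. A single integer seed makes the whole draw, and hence
the whole pipeline, reproducible byte for byte.

What it does not emulate: peptide-level quantification and shared peptides,
batch/run-order effects, correlated noise between hemispheres of the same
specimen, and intensity-dependent noise variance. Tests passing on this
generator therefore certify the screening logic and calibration of the
statistics under idealized missingness, not robustness to those real-data
artifacts.

`fixture_small` is a ≤ 200-protein preset with boosted effect fractions; it
deterministically sweeps a handful of derived seeds until every truth label is
realized and the core set is non-empty.

## Problem sizes in the validation suite

The test suite validates calibration claims at deliberately modest sizes
chosen to estimate each quantity stably: 5,000 ratios for significance-A
calibration, 5,000 proteins for prior-df recovery (within 25%), 50 seeds ×
800 null proteins for type-I error of the DEP calls, 10 seeds × 3,000
proteins for AEP recovery (sensitivity ≥ 0.9, FDR ≤ 0.1 at a planted 4-fold
effect), and 100 seeded runs of 100 exchangeable trajectories for the
profile-null flag rate.

## Known limitations

* With a single specimen per timepoint, "differential between weeks" is
  confounded with individual differences; the moderated test quantifies
  measurement plus biological residual, not inter-individual variation.
* significance-A p-values are not multiplicity-corrected (by design, matching
  the screening convention); the p < 0.05 cut is a screen, not an FDR
  guarantee, and each tail flags ~5% of a well-behaved null.
* The 1st-percentile floor is estimated from the same week it filters, so
  with few detected proteins it is noisy.
* Profile enrichment p-values use the binomial approximation described above
  and inherit discreteness at small N.
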