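"""Timepoint differential expression with empirical-Bayes variance moderation.

The left and right samples of each gestational week are pooled as replicates
(the tissue is treated as a whole), giving a one-way layout with a timepoint
factor.  Per-protein residual variances are shrunk toward a common prior by
moment matching on log variances: if s_g^2 ~ s0^2 * F(d_g, d0), then
z = log s_g^2 has Var(z) = trigamma(d_g/2) + trigamma(d0/2), which is solved
for the prior degrees of freedom d0; the posterior (moderated) variance is

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

and the moderated t-statistic has d_g + d0 degrees of freedom (a normal tail
when d0 is infinite).  Calls use strict thresholds: |log2FC| > log2(fc) and
BH-adjusted FDR < the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateStatisticError, DesignError
from .quant_io import SampleDesign

log = logging.getLogger(__name__)


@dataclass
class FitResult:
    """Per-protein one-way fit: group means, consecutive-week contrasts, residual variance."""

    means: pd.DataFrame  # proteins x gw group means (log2 scale)
    contrasts: pd.DataFrame  # proteins x interval labels, later minus earlier
    v: dict[str, float]  # interval -> unscaled contrast variance 1/n_a + 1/n_b
    s2: pd.Series  # pooled within-group variance per protein
    df_resid: int  # n_samples - n_timepoints


@dataclass
class ModerationFit:
    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance
    s2: pd.Series  # raw per-protein variances
    df_resid: int
    s_tilde_sq: pd.Series  # moderated variances

    @property
    def degenerate(self) -> bool:
        return np.isinf(self.d0) and self.s0_sq == 0


def interval_label(gw_a: int, gw_b: int) -> str:
    return f"{gw_a}:{gw_b}"


def fit_models(lm: pd.DataFrame, design: SampleDesign) -> FitResult:
    """One-way timepoint model on a complete log2 matrix (core set).

    Columns of ``lm`` are sample ids known to ``design``; every timepoint needs
    at least two samples to contribute residual degrees of freedom.
    """
    gw_of = design.frame["gw"]
    missing = [c for c in lm.columns if c not in gw_of.index]
    if missing:
        raise DesignError(f"samples without design entry: {missing}")
    gws = sorted(set(int(gw_of[c]) for c in lm.columns))
    groups = {gw: [c for c in lm.columns if int(gw_of[c]) == gw] for gw in gws}
    sizes = {gw: len(cols) for gw, cols in groups.items()}
    thin = [gw for gw, n in sizes.items() if n < 2]
    if thin:
        raise DesignError(f"timepoint(s) {thin} have < 2 samples: no residual df")

    means = pd.DataFrame({gw: lm[groups[gw]].mean(axis=1) for gw in gws})
    rss = sum(
        ((lm[groups[gw]].to_numpy() - means[gw].to_numpy()[:, None]) ** 2).sum(axis=1)
        for gw in gws
    )
    df_resid = lm.shape[1] - len(gws)
    s2 = pd.Series(rss / df_resid, index=lm.index, name="s2")

    contrasts = {}
    v = {}
    for gw_a, gw_b in zip(gws[:-1], gws[1:]):
        lab = interval_label(gw_a, gw_b)
        contrasts[lab] = means[gw_b] - means[gw_a]  # later minus earlier
        v[lab] = 1.0 / sizes[gw_a] + 1.0 / sizes[gw_b]
    return FitResult(means, pd.DataFrame(contrasts), v, s2, df_resid)


def moderate_variances(s2: pd.Series, df_resid: int) -> ModerationFit:
    """Estimate (d0, s0^2) by moment matching on log variances and shrink.

    Zero variances cannot enter the log-moment fit and are excluded from it,
    but are still moderated.  If the observed dispersion of log variances does
    not exceed what d_g alone explains, d0 is infinite and every moderated
    variance equals s0^2.
    """
    s2 = pd.Series(s2).astype(float)
    pos = s2[s2 > 0]
    if (s2 < 0).any():
        raise DataError("negative variance")
    n_zero = len(s2) - len(pos)
    if n_zero:
        log.info("excluding %d zero-variance protein(s) from the moment fit", n_zero)
    if len(pos) < 2:
        # all-zero (or near) input: flagged degenerate, t undefined downstream
        fit = ModerationFit(np.inf, 0.0, s2, df_resid, pd.Series(0.0, index=s2.index))
        return fit

    z = np.log(pos.to_numpy())
    half_dg = df_resid / 2.0
    e = z - special.digamma(half_dg) + np.log(half_dg)
    var_e = float(np.var(e, ddof=1))
    rhs = var_e - float(special.polygamma(1, half_dg))

    if rhs <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        def f(d0_):
            return float(special.polygamma(1, d0_ / 2.0)) - rhs

        lo, hi = 1e-6, 1e6
        if f(hi) > 0:  # dispersion below trigamma(hi/2): effectively infinite d0
            d0, s0_sq = np.inf, float(np.exp(np.mean(e)))
        else:
            d0 = float(optimize.brentq(f, lo, hi, xtol=1e-8))
            s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    s_tilde = moderated_variance(s2, df_resid, d0, s0_sq)
    return ModerationFit(d0, s0_sq, s2, df_resid, s_tilde)


def moderated_variance(s2: pd.Series, df_resid: float, d0: float, s0_sq: float) -> pd.Series:
    if np.isinf(d0):
        return pd.Series(s0_sq, index=s2.index)
    return (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)


def moderated_t(
    contrast: pd.Series | np.ndarray,
    v: float,
    fit: ModerationFit,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistic and two-sided p for one contrast.

    t = contrast / sqrt(s~^2 * v) on d_g + d0 degrees of freedom.
    """
    contrast = np.asarray(contrast, float)
    s_tilde = fit.s_tilde_sq.to_numpy()
    if (s_tilde <= 0).any():
        raise DegenerateStatisticError("moderated variance is zero: t undefined")
    t = contrast / np.sqrt(s_tilde * v)
    df_total = fit.df_resid + fit.d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving with input."""
    arr = np.asarray(p, float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_table(fit: FitResult, mod: ModerationFit) -> pd.DataFrame:
    """Full per-protein, per-interval differential table with BH-FDR per interval."""
    frames = []
    for lab in fit.contrasts.columns:
        t, p = moderated_t(fit.contrasts[lab], fit.v[lab], mod)
        frames.append(
            pd.DataFrame(
                {
                    "protein": fit.contrasts.index,
                    "interval": lab,
                    "log2FC": fit.contrasts[lab].to_numpy(),
                    "t_mod": t,
                    "p": p,
                    "fdr": bh_adjust(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_deps(
    results: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Attach up/down/ns calls (strict thresholds) to a differential table."""
    out = results.copy()
    lfc_cut = np.log2(fc_threshold)
    up = (out["log2FC"] > lfc_cut) & (out["fdr"] < fdr_threshold)
    down = (out["log2FC"] < -lfc_cut) & (out["fdr"] < fdr_threshold)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def percent_of(count: int, total: int, digits: int = 2) -> float:
    """Share of a count in a total, as a percentage rounded for reporting."""
    if total <= 0:
        raise DataError("total must be positive")
    return round(100.0 * count / total, digits)


def dep_summary(called: pd.DataFrame, core_size: int) -> pd.DataFrame:
    """Per-interval up/down/total DEP counts and their share of the core set."""
    rows = []
    for lab, sub in called.groupby("interval", sort=False):
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        rows.append(
            {
                "interval": lab,
                "n_up": n_up,
                "n_down": n_down,
                "n_dep": n_up + n_down,
                "core_size": core_size,
                "percent_of_core": percent_of(n_up + n_down, core_size),
            }
        )
    return pd.DataFrame(rows)
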