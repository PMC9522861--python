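"""Per-timepoint left/right screening.

Three ingredients decide laterality calls at each gestational week:

* the asymmetry index AI = (L - R)/(L + R), which is +1 for left-only and
  -1 for right-only proteins;
* the significance-A outlier test on log2(L/R): robust z-scores built from the
  15.87th/50th/84.13th percentiles of the per-week ratio distribution, with a
  one-sided tail probability p = erfc(z/sqrt(2))/2 per side (no doubling);
* an intensity credibility floor, the 1st percentile of the bilaterally
  averaged intensities of detected proteins, below which asymmetric or
  unilateral calls are deemed unreliable and re-classed ``low_intensity``.

A protein detected on both sides is an AEP when its raw LFQ fold change
exceeds the threshold (strict >) and its significance-A p is below the cutoff
(strict <); a protein with zero intensity on exactly one side is a unilateral
call.  Fold changes are computed on raw LFQ intensities, not log-transformed
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import erfc

from .errors import DataError, ParameterError
from .quant_io import DesignedMatrix

log = logging.getLogger(__name__)

AEP_CLASSES = ("aep_left", "aep_right")
UNILATERAL_CLASSES = ("unilateral_left", "unilateral_right")


def asymmetry_index(L, R):
    """AI = (L - R)/(L + R); undefined when both sides are zero."""
    L = np.asarray(L, float)
    R = np.asarray(R, float)
    if np.any(L < 0) or np.any(R < 0):
        raise DataError("intensities must be non-negative")
    total = L + R
    if np.any(total == 0):
        raise DataError("AI undefined when L = R = 0")
    out = (L - R) / total
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SigAQuantiles:
    """Robust location/scale summary of a log-ratio distribution."""

    r_minus1: float  # 15.87th percentile
    r0: float  # median
    r1: float  # 84.13th percentile

    def __post_init__(self):
        if not (self.r_minus1 <= self.r0 <= self.r1):
            raise DataError("quantiles must be ordered r_-1 <= r0 <= r1")


def sig_a_p(x, quantiles: SigAQuantiles) -> np.ndarray:
    """Significance-A outlier probability at arbitrary log-ratio value(s).

    z is side-specific: (x - r0)/(r1 - r0) above the median and
    (r0 - x)/(r0 - r_-1) below; p = erfc(z/sqrt(2))/2, so p = 0.5 at the
    median.  A degenerate (zero-width) side yields p = 1 on that side.
    """
    x = np.atleast_1d(np.asarray(x, float))
    up = quantiles.r1 - quantiles.r0
    dn = quantiles.r0 - quantiles.r_minus1
    p = np.full(x.shape, np.nan)
    above = x >= quantiles.r0
    if up > 0:
        z = (x[above] - quantiles.r0) / up
        p[above] = 0.5 * erfc(z / np.sqrt(2.0))
    else:
        if above.any():
            log.warning("degenerate upper spread (r1 == r0): p = 1 on that side")
        p[above] = 1.0
    below = ~above
    if dn > 0:
        z = (quantiles.r0 - x[below]) / dn
        p[below] = 0.5 * erfc(z / np.sqrt(2.0))
    else:
        if below.any():
            log.warning("degenerate lower spread (r0 == r_-1): p = 1 on that side")
        p[below] = 1.0
    return p


def significance_a(log_ratios) -> tuple[SigAQuantiles, np.ndarray]:
    """Quantiles and per-ratio outlier p for one week's log-ratio distribution."""
    x = np.asarray(log_ratios, float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise DataError("significance A needs >= 2 finite log-ratios")
    if finite.sum() < 20:
        log.warning("only %d finite log-ratios: significance A is low-powered", finite.sum())
    r_m1, r0, r1 = np.percentile(x[finite], [15.87, 50.0, 84.13])
    quantiles = SigAQuantiles(float(r_m1), float(r0), float(r1))
    p = np.full(x.shape, np.nan)
    p[finite] = sig_a_p(x[finite], quantiles)
    return quantiles, p


def intensity_floor(mean_intensities, percentile: float = 1.0) -> float:
    """Credibility floor: a low percentile of bilaterally averaged intensities.

    Computed over detected proteins (L + R > 0) with the linear-interpolation
    percentile convention.
    """
    vals = np.asarray(mean_intensities, float)
    vals = vals[vals > 0]
    if vals.size < 2:
        raise DataError("intensity floor needs >= 2 detected proteins")
    return float(np.percentile(vals, percentile))


def asymmetry_records(
    dm: DesignedMatrix,
    gw: int,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    floor_percentile: float = 1.0,
) -> pd.DataFrame:
    """Full per-protein laterality table at one gestational week.

    Covers every detected protein (L + R > 0) and classifies each into exactly
    one of: aep_left, aep_right, unilateral_left, unilateral_right,
    bilateral_ns, low_intensity.  The floor suppresses asymmetric and
    unilateral calls only; symmetric bilateral proteins keep ``bilateral_ns``.
    """
    L = dm.column("L", gw).to_numpy(float)
    R = dm.column("R", gw).to_numpy(float)
    ids = np.asarray(dm.protein_ids)
    detected = (L + R) > 0
    L, R, ids = L[detected], R[detected], ids[detected]

    mean_intensity = (L + R) / 2.0
    ai = (L - R) / (L + R)
    both = (L > 0) & (R > 0)
    log2_ratio = np.full(L.shape, np.nan)
    log2_ratio[both] = np.log2(L[both] / R[both])
    fold = np.full(L.shape, np.inf)  # one-sided detection: infinite fold change
    fold[both] = np.maximum(L[both] / R[both], R[both] / L[both])

    p = np.full(L.shape, np.nan)
    if both.sum() >= 2:
        _, p_both = significance_a(log2_ratio[both])
        p[both] = p_both
    floor = intensity_floor(mean_intensity, floor_percentile)

    cls = np.full(L.shape, "bilateral_ns", dtype=object)
    aep_left = both & (np.divide(L, R, out=np.zeros_like(L), where=R > 0) > fc_threshold) & (p < p_threshold)
    aep_right = both & (np.divide(R, L, out=np.zeros_like(R), where=L > 0) > fc_threshold) & (p < p_threshold)
    cls[aep_left] = "aep_left"
    cls[aep_right] = "aep_right"
    cls[(L > 0) & (R == 0)] = "unilateral_left"
    cls[(L == 0) & (R > 0)] = "unilateral_right"
    suppress = (cls != "bilateral_ns") & (mean_intensity < floor)
    cls[suppress] = "low_intensity"

    return pd.DataFrame(
        {
            "protein": ids,
            "gw": gw,
            "L": L,
            "R": R,
            "mean_intensity": mean_intensity,
            "ai": ai,
            "log2_ratio": log2_ratio,
            "sig_a_p": p,
            "fold_change": fold,
            "class": cls,
        }
    )


def call_aeps(
    dm: DesignedMatrix,
    gw: int,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    floor_percentile: float = 1.0,
) -> pd.DataFrame:
    """Laterality records for proteins detected on both sides at one week."""
    rec = asymmetry_records(dm, gw, fc_threshold, p_threshold, floor_percentile)
    return rec[(rec["L"] > 0) & (rec["R"] > 0)].reset_index(drop=True)


def call_unilateral(dm: DesignedMatrix, gw: int, floor_percentile: float = 1.0) -> pd.DataFrame:
    """Records for proteins with zero intensity on exactly one side at one week."""
    rec = asymmetry_records(dm, gw, floor_percentile=floor_percentile)
    one_side = ((rec["L"] > 0) & (rec["R"] == 0)) | ((rec["L"] == 0) & (rec["R"] > 0))
    return rec[one_side].reset_index(drop=True)


@dataclass
class SharedAsymmetry:
    """Cross-timepoint laterality: repeated AEPs and a relaxed every-week fold rule."""

    shared: pd.DataFrame  # proteins AEP (full rule) in >= min_gws weeks
    pairwise_counts: pd.DataFrame  # exactly-two decomposition per week pair
    consistent_fold: pd.DataFrame  # fold change >= fc_threshold at every week
    min_gws: int
    fc_threshold: float


def shared_asymmetric(
    records_by_gw: Mapping[int, pd.DataFrame],
    min_gws: int = 2,
    fc_threshold: float = 1.5,
) -> SharedAsymmetry:
    """Proteins asymmetric at multiple weeks, plus the relaxed fold-only rule.

    The full rule counts weeks at which a protein carries an AEP class
    (fold > 2 and significance-A p < 0.05, floor applied); the relaxed rule
    requires only a raw fold change >= ``fc_threshold`` (inclusive, as a
    screening criterion; no significance requirement) at *every* week, with
    per-week direction recorded but not required consistent.
    """
    gws = sorted(records_by_gw)
    if min_gws > len(gws):
        raise ParameterError(f"min_gws={min_gws} exceeds {len(gws)} timepoints")
    if min_gws < 2:
        raise ParameterError("min_gws must be >= 2")

    aep_weeks: dict[str, list[int]] = {}
    fold_at: dict[str, dict[int, float]] = {}
    dir_at: dict[str, dict[int, str]] = {}
    for gw in gws:
        rec = records_by_gw[gw]
        for _, row in rec.iterrows():
            pid = row["protein"]
            if row["class"] in AEP_CLASSES:
                aep_weeks.setdefault(pid, []).append(gw)
            if row["L"] > 0 and row["R"] > 0:
                fold_at.setdefault(pid, {})[gw] = float(row["fold_change"])
                dir_at.setdefault(pid, {})[gw] = "left" if row["L"] > row["R"] else "right"

    shared_rows = []
    for pid, weeks in sorted(aep_weeks.items()):
        if len(weeks) >= min_gws:
            row = {"protein": pid, "n_gws_aep": len(weeks), "gws_aep": ",".join(map(str, weeks))}
            for gw in gws:
                row[f"fold_gw{gw}"] = fold_at.get(pid, {}).get(gw, np.nan)
                row[f"direction_gw{gw}"] = dir_at.get(pid, {}).get(gw, "")
            shared_rows.append(row)
    shared = pd.DataFrame(shared_rows)

    pair_rows = []
    for gw_a, gw_b in combinations(gws, 2):
        n = sum(1 for weeks in aep_weeks.values() if set(weeks) == {gw_a, gw_b})
        pair_rows.append({"gw_a": gw_a, "gw_b": gw_b, "n_exactly_two": n})
    pairwise = pd.DataFrame(pair_rows)

    cons_rows = []
    for pid in sorted(fold_at):
        folds = fold_at[pid]
        if set(folds) == set(gws) and all(folds[gw] >= fc_threshold for gw in gws):
            row = {"protein": pid}
            for gw in gws:
                row[f"fold_gw{gw}"] = folds[gw]
                row[f"direction_gw{gw}"] = dir_at[pid][gw]
            cons_rows.append(row)
    consistent = pd.DataFrame(cons_rows)

    return SharedAsymmetry(shared, pairwise, consistent, min_gws, fc_threshold)
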