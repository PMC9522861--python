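"""Detection sets, core protein set, overlap counts, log2 transform and sample summaries.

"Detected" means LFQ intensity > 0.  The core protein set is the set of
proteins detected in every sample of the study; downstream differential and
profile analyses operate on it because it has no missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataError
from .quant_io import HEMISPHERES, DesignedMatrix

log = logging.getLogger(__name__)


@dataclass
class DetectionSummary:
    """Detected-protein sets per sample, per-week bilateral sets, and the core set."""

    per_sample: dict[tuple[str, int], set[str]]  # (hemisphere, gw) -> detected ids
    bilateral: dict[int, set[str]]  # gw -> detected on both sides
    core: set[str]  # detected in every sample

    def counts(self) -> pd.DataFrame:
        rows = [
            {"hemisphere": h, "gw": gw, "n_detected": len(ids)}
            for (h, gw), ids in sorted(self.per_sample.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        ]
        for gw in sorted(self.bilateral):
            rows.append({"hemisphere": "both", "gw": gw, "n_detected": len(self.bilateral[gw])})
        rows.append({"hemisphere": "core", "gw": 0, "n_detected": len(self.core)})
        return pd.DataFrame(rows)


def detection_sets(dm: DesignedMatrix) -> DetectionSummary:
    """Classify detection (> 0) per sample; derive bilateral and core sets."""
    per_sample: dict[tuple[str, int], set[str]] = {}
    index = dm.matrix.intensities.index
    for gw in dm.gws:
        for h in HEMISPHERES:
            col = dm.column(h, gw)
            per_sample[(h, gw)] = set(index[col.to_numpy() > 0])
    bilateral = {gw: per_sample[("L", gw)] & per_sample[("R", gw)] for gw in dm.gws}
    core = set(index)
    for ids in per_sample.values():
        core &= ids
    return DetectionSummary(per_sample, bilateral, core)


def overlap_counts(sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """All intersection-region cardinalities for >= 2 named sets.

    For every non-empty combination of names the table reports the plain
    intersection size and the exclusive region size (elements in exactly those
    sets and no others); exclusive counts partition the union.
    """
    if len(sets) < 2:
        raise DataError("overlap_counts needs at least 2 sets")
    names = list(sets)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(set(sets[c]) for c in combo))
            others = set().union(*(sets[n] for n in names if n not in combo)) if k < len(names) else set()
            rows.append(
                {
                    "sets": "&".join(combo),
                    "degree": k,
                    "intersection": len(inter),
                    "exclusive": len(inter - others),
                }
            )
    return pd.DataFrame(rows)


def log2_normalize(dm: DesignedMatrix, restrict_to: Iterable[str]) -> pd.DataFrame:
    """log2-transform intensities of the given proteins (no centering or scaling).

    Every restricted protein must be detected in every sample, so the result
    has no gaps; fold changes are unchanged by construction.
    """
    ids = [p for p in dm.matrix.intensities.index if p in set(restrict_to)]
    sub = dm.matrix.intensities.loc[ids]
    zero_rows = sub.index[(sub.to_numpy() <= 0).any(axis=1)]
    if len(zero_rows):
        raise DataError(f"zero intensity within restriction for protein {zero_rows[0]!r}")
    return np.log2(sub)


@dataclass
class PCASummary:
    percent_variance: np.ndarray  # per PC, sums to 100
    sample_scores: pd.DataFrame  # samples x PCs
    dropped_proteins: list[str]


def pca_summary(lm: pd.DataFrame) -> PCASummary:
    """Correlation-matrix PCA with proteins as observations and samples as variables.

    Sample columns are standardized (mean 0, unit variance, ddof=1) so the
    analysed covariance is the sample correlation matrix; per-sample scores are
    the variable loadings scaled by the PC standard deviation (the correlation
    of each sample with each component).
    """
    if lm.shape[1] < 2:
        raise DataError("PCA needs >= 2 samples")
    row_var = lm.var(axis=1, ddof=0)
    dropped = list(lm.index[row_var == 0])
    if dropped:
        log.warning("dropping %d constant protein(s) from PCA", len(dropped))
    X = lm.loc[row_var > 0].to_numpy(float)
    if X.shape[0] < 2:
        raise DataError("PCA needs >= 2 non-constant proteins")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n_pc = min(Z.shape)
    fit = PCA(n_components=n_pc, svd_solver="full").fit(Z)
    percent = 100.0 * fit.explained_variance_ratio_
    scores = fit.components_.T * np.sqrt(fit.explained_variance_)
    pcs = [f"PC{i + 1}" for i in range(n_pc)]
    return PCASummary(percent, pd.DataFrame(scores, index=lm.columns, columns=pcs), dropped)


def sample_correlation(lm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between sample columns (proteins as observations)."""
    if lm.shape[0] < 2:
        raise DataError("correlation needs >= 2 proteins")
    const = [c for c in lm.columns if lm[c].nunique() == 1]
    if const:
        log.warning("zero-variance sample column(s) %s: correlation undefined (NaN)", const)
    return lm.corr(method="pearson")
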