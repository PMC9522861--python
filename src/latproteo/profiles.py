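"""Short time-series profile clustering of core-protein trajectories.

With only a handful of ordered timepoints, trajectories are clustered against
a fixed library of integer-step model profiles (the STEM approach): every
shape starts at 0 and moves by at most ``c`` units per step, a distinct subset
of ``m`` shapes is chosen by greedy max-min correlation distance, each protein
series (expressed as differences from its first timepoint) is assigned to the
most correlated model shape, and per-profile enrichment is judged against the
exact permutation null obtained by recomputing assignments under all T!
orderings of each protein's values.  Everything is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ParameterError
from .quant_io import SampleDesign

MAX_EXACT_PERMUTATIONS = 5000  # exact T! enumeration only (T <= 7)


@dataclass(frozen=True)
class ProfileModel:
    profile_id: int
    shape: tuple[int, ...]  # starts at 0, steps in [-c, c]


@dataclass
class ProfileSet:
    models: list[ProfileModel]
    assignment: pd.Series  # protein -> profile_id
    table: pd.DataFrame  # profile_id, shape, n, expected, p, significant
    alpha: float


def enumerate_candidates(T: int, c: int) -> list[ProfileModel]:
    """All (2c+1)^(T-1) integer-step shapes starting at 0, in deterministic order."""
    if T < 2 or c < 1:
        raise ParameterError("need T >= 2 and c >= 1")
    models = []
    for i, steps in enumerate(product(range(-c, c + 1), repeat=T - 1)):
        shape = (0, *np.cumsum(steps).tolist())
        models.append(ProfileModel(i, tuple(int(v) for v in shape)))
    return models


def _shape_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the flat-profile convention.

    A zero-variance vector is the flat profile: its correlation with any
    non-constant vector is 0, and with another constant vector 1.
    """
    sa, sb = a.std(), b.std()
    if sa == 0 and sb == 0:
        return 1.0
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def select_model_profiles(candidates: list[ProfileModel], m: int) -> list[ProfileModel]:
    """Greedy max-min selection of m mutually dissimilar shapes.

    Seeds with the flat profile, then repeatedly adds the candidate whose
    minimum distance d = 1 - r to the selected set is largest, breaking ties
    by lowest enumeration index.  Distances are rounded to 12 decimals before
    comparison so that ties exact in real arithmetic (integer shapes give
    rational correlations) are not broken by floating-point noise.  Selected
    models are re-numbered densely from 0 in enumeration order.
    """
    if not (1 <= m <= len(candidates)):
        raise ParameterError(f"m must be in [1, {len(candidates)}]")
    shapes = [np.asarray(mod.shape, float) for mod in candidates]
    flat = next(i for i, s in enumerate(shapes) if s.std() == 0)
    selected = [flat]
    dist = np.round([1.0 - _shape_corr(s, shapes[flat]) for s in shapes], 12)
    dist[flat] = -np.inf
    while len(selected) < m:
        best = int(np.argmax(dist))  # argmax takes the first (lowest index) on ties
        selected.append(best)
        new = np.round([1.0 - _shape_corr(s, shapes[best]) for s in shapes], 12)
        dist = np.minimum(dist, new)
        dist[best] = -np.inf
    chosen = sorted(selected)
    return [ProfileModel(j, candidates[i].shape) for j, i in enumerate(chosen)]


def _assign_matrix(series: np.ndarray, models: list[ProfileModel]) -> np.ndarray:
    """Assign each row to the model with maximal correlation to its shape.

    Rows are first transformed to differences from their own first timepoint.
    Constant rows go to the flat profile; correlation with the flat profile is
    0 for non-constant rows.  Ties break toward the lowest profile_id.
    """
    diffs = series - series[:, [0]]
    centered = diffs - diffs.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0

    corr = np.zeros((series.shape[0], len(models)))
    flat_id = None
    for j, mod in enumerate(models):
        s = np.asarray(mod.shape, float)
        sc = s - s.mean()
        sn = np.sqrt((sc**2).sum())
        if sn == 0:
            flat_id = j
            continue  # corr with flat stays 0 for non-constant rows
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[:, j] = (centered @ sc) / (norms * sn)
    corr[constant, :] = -np.inf
    assigned = np.argmax(corr, axis=1)  # first max wins: lowest profile_id
    if flat_id is None and constant.any():
        raise ParameterError("constant series need the flat profile among the models")
    if constant.any():
        assigned[constant] = flat_id
    return assigned


def assign_proteins(series: pd.DataFrame, models: list[ProfileModel]) -> pd.Series:
    """Per-protein model-profile assignment for a complete trajectory matrix."""
    ids = [m.profile_id for m in models]
    if ids != list(range(len(models))):
        raise ParameterError("model profile_ids must be dense from 0")
    assigned = _assign_matrix(series.to_numpy(float), models)
    return pd.Series(assigned, index=series.index, name="profile_id")


def profile_significance(
    series: pd.DataFrame, models: list[ProfileModel], alpha: float = 0.05
) -> ProfileSet:
    """Exact permutation expected counts and binomial enrichment p per profile.

    For every protein the assignment is recomputed under all T! orderings of
    its observed values; E_j is the mean assignment mass per profile, and
    p_j = P(X >= n_j) for X ~ Binomial(N, E_j/N) (inclusive upper tail).
    """
    X = series.to_numpy(float)
    N, T = X.shape
    if math.factorial(T) > MAX_EXACT_PERMUTATIONS:
        raise ParameterError(f"exact enumeration only: T! must be <= {MAX_EXACT_PERMUTATIONS}")
    assignment = assign_proteins(series, models)
    n_models = len(models)

    counts = np.zeros(n_models)
    perms = list(permutations(range(T)))
    for perm in perms:
        assigned = _assign_matrix(X[:, perm], models)
        counts += np.bincount(assigned, minlength=n_models)
    expected = counts / len(perms)

    n_obs = np.bincount(assignment.to_numpy(), minlength=n_models)
    p = np.array(
        [stats.binom.sf(n_obs[j] - 1, N, expected[j] / N) if N else 1.0 for j in range(n_models)]
    )
    table = pd.DataFrame(
        {
            "profile_id": [m.profile_id for m in models],
            "shape": [",".join(map(str, m.shape)) for m in models],
            "n": n_obs,
            "expected": expected,
            "p": p,
            "significant": p <= alpha,
        }
    )
    return ProfileSet(models, assignment, table, alpha)


def run_profiles(
    lm: pd.DataFrame,
    design: SampleDesign,
    side: str,
    c: int = 2,
    m: int = 16,
    alpha: float = 0.05,
) -> ProfileSet:
    """Full per-hemisphere profile clustering of a complete log2 matrix.

    ``lm`` columns are sample ids; exactly one sample per gestational week must
    exist for the chosen side.  Left and right runs are independent.
    """
    gws = design.gws
    try:
        cols = [design.sample_for(side, gw) for gw in gws]
    except Exception as exc:
        raise DesignError(f"side {side!r}: {exc}") from exc
    missing = [c_ for c_ in cols if c_ not in lm.columns]
    if missing:
        raise DesignError(f"samples {missing} absent from matrix")
    series = lm[cols].copy()
    series.columns = gws
    candidates = enumerate_candidates(len(gws), c)
    models = select_model_profiles(candidates, m)
    return profile_significance(series, models, alpha)
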