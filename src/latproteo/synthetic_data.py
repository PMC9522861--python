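"""Synthetic paired left/right LFQ matrices with known planted structure.

The generator emulates a label-free shotgun proteomics study of paired
left/right brain tissue across gestational weeks: one fetus per timepoint, so
exactly one L and one R column per week.  Per-protein log2 abundance is a
baseline plus a temporal trend plus an optional hemisphere effect plus noise;
realized intensities then suffer logistic dropout concentrated at low
abundance, which is what makes the low-intensity credibility filter and the
core-set construction non-trivial downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError
from .quant_io import DesignedMatrix, QuantMatrix, SampleDesign, join_design

#: label values used in the truth table, per protein per timepoint
LABELS = ("aep_left", "aep_right", "unilateral_left", "unilateral_right", "null")

#: default temporal shapes on the log2 scale at the ordered timepoints,
#: with assignment fractions.  "late" shapes change only after the middle week.
DEFAULT_TRENDS: Mapping[str, tuple[tuple[float, ...], float]] = {
    "flat": ((0.0, 0.0, 0.0), 0.60),
    "up": ((0.0, 0.75, 1.5), 0.10),
    "down": ((0.0, -0.75, -1.5), 0.10),
    "late_up": ((0.0, 0.0, 1.5), 0.10),
    "late_down": ((0.0, 0.0, -1.5), 0.10),
}


@dataclass
class SimParams:
    """Parameters of the generative model.

    Defaults mirror the structure of the real study: ~3,000 protein groups,
    six samples (L/R x GW 9/11/13), log2 LFQ baselines around 25 with sd 2,
    a few percent of proteins asymmetric per week at a >2-fold planted effect,
    and logistic dropout with 50% detection around log2 intensity 20 so that
    missingness concentrates at low abundance.
    """

    n_proteins: int = 3000
    gws: Sequence[int] = (9, 11, 13)
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    frac_aep: float = 0.05  # per-timepoint fraction with an L/R effect
    aep_log2_effect: float = 1.5
    frac_unilateral: float = 0.05
    trend_profiles: Mapping[str, tuple[tuple[float, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_TRENDS)
    )
    noise_log2_sd: float = 0.25
    dropout_midpoint: float | None = 20.0  # None disables dropout
    dropout_slope: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be >= 1")
        if len(self.gws) < 2 or len(set(self.gws)) != len(self.gws):
            raise ParameterError("gws must be >= 2 distinct timepoints")
        if not (0 <= self.frac_aep <= 1 and 0 <= self.frac_unilateral <= 1):
            raise ParameterError("fractions must lie in [0, 1]")
        if self.frac_aep + self.frac_unilateral > 1:
            raise ParameterError("frac_aep + frac_unilateral must be <= 1")
        if self.base_log2_sd <= 0 or self.noise_log2_sd < 0:
            raise ParameterError("standard deviations must be positive")
        if self.dropout_midpoint is not None and self.dropout_slope <= 0:
            raise ParameterError("dropout_slope must be > 0")
        T = len(self.gws)
        fracs = [f for _, f in self.trend_profiles.values()]
        if not self.trend_profiles or any(f < 0 for f in fracs) or sum(fracs) <= 0:
            raise ParameterError("trend_profiles need non-negative fractions summing > 0")
        for name, (shape, _) in self.trend_profiles.items():
            if len(shape) != T:
                raise ParameterError(f"trend {name!r} must have {T} values")


@dataclass
class TruthTable:
    """Planted ground truth: per-protein baselines/trends and per-(protein, gw) labels."""

    per_protein: pd.DataFrame  # index protein id; baseline, trend, role, side
    per_timepoint: pd.DataFrame  # columns: protein, gw, true_log2_l, true_log2_r, label

    def labels(self, gw: int) -> pd.Series:
        sub = self.per_timepoint[self.per_timepoint["gw"] == gw]
        return sub.set_index("protein")["label"]

    def proteins_with_label(self, label: str, gw: int | None = None) -> set[str]:
        sub = self.per_timepoint
        if gw is not None:
            sub = sub[sub["gw"] == gw]
        return set(sub.loc[sub["label"] == label, "protein"])

    def label_census(self) -> pd.Series:
        return self.per_timepoint["label"].value_counts()


def generate(params: SimParams) -> tuple[QuantMatrix, SampleDesign, TruthTable]:
    """Draw one synthetic study: intensity matrix, design and planted truth.

    Identical params (including seed) yield identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    gws = [int(g) for g in params.gws]
    T = len(gws)

    baseline = rng.normal(params.base_log2_mean, params.base_log2_sd, size=n)

    trend_names = list(params.trend_profiles)
    trend_fracs = np.array([params.trend_profiles[t][1] for t in trend_names], float)
    trend_fracs = trend_fracs / trend_fracs.sum()
    trend_idx = rng.choice(len(trend_names), size=n, p=trend_fracs)
    trend_shapes = np.array([params.trend_profiles[t][0] for t in trend_names], float)
    trend = trend_shapes[trend_idx]  # (n, T) log2 offsets

    # protein roles: unilateral proteins are zero on one side at every week;
    # the rest may carry a per-week L/R fold-change effect
    u = rng.random(n)
    is_unilateral = u < params.frac_unilateral
    side = np.where(rng.random(n) < 0.5, "L", "R")  # effect / retained side
    aep_flags = (rng.random((n, T)) < params.frac_aep) & ~is_unilateral[:, None]

    mu_l = baseline[:, None] + trend
    mu_r = mu_l.copy()
    left_effect = (side == "L")[:, None] & aep_flags
    right_effect = (side == "R")[:, None] & aep_flags
    mu_l = mu_l + params.aep_log2_effect * left_effect
    mu_r = mu_r + params.aep_log2_effect * right_effect

    eps_l = rng.normal(0.0, params.noise_log2_sd, size=(n, T)) if params.noise_log2_sd else 0.0
    eps_r = rng.normal(0.0, params.noise_log2_sd, size=(n, T)) if params.noise_log2_sd else 0.0
    log_l = mu_l + eps_l
    log_r = mu_r + eps_r
    intens_l = np.exp2(log_l)
    intens_r = np.exp2(log_r)

    if params.dropout_midpoint is not None:
        p_drop_l = expit((params.dropout_midpoint - log_l) * params.dropout_slope)
        p_drop_r = expit((params.dropout_midpoint - log_r) * params.dropout_slope)
        intens_l = np.where(rng.random((n, T)) < p_drop_l, 0.0, intens_l)
        intens_r = np.where(rng.random((n, T)) < p_drop_r, 0.0, intens_r)

    # unilateral proteins: forced undetected on the non-retained side everywhere
    intens_l[is_unilateral & (side == "R"), :] = 0.0
    intens_r[is_unilateral & (side == "L"), :] = 0.0

    width = max(len(str(n)), 4)
    protein_ids = [f"P{i:0{width}d}" for i in range(n)]
    sample_ids = [f"{h}{gw:02d}" for gw in gws for h in ("L", "R")]
    data = np.empty((n, 2 * T))
    for j, gw in enumerate(gws):
        data[:, 2 * j] = intens_l[:, j]
        data[:, 2 * j + 1] = intens_r[:, j]
    intensities = pd.DataFrame(
        data, index=pd.Index(protein_ids, name="protein_group_id"), columns=sample_ids
    )
    meta = pd.DataFrame(
        {"gene_name": [f"GENE{i}" for i in range(n)], "majority_ids": protein_ids},
        index=intensities.index,
    )
    matrix = QuantMatrix(intensities, meta)
    design = SampleDesign.from_mapping(
        {f"{h}{gw:02d}": (h, gw) for gw in gws for h in ("L", "R")}
    )

    labels = np.full((n, T), "null", dtype=object)
    labels[aep_flags & (side == "L")[:, None]] = "aep_left"
    labels[aep_flags & (side == "R")[:, None]] = "aep_right"
    labels[is_unilateral & (side == "L"), :] = "unilateral_left"
    labels[is_unilateral & (side == "R"), :] = "unilateral_right"

    role = np.where(is_unilateral, "unilateral", np.where(aep_flags.any(axis=1), "aep", "null"))
    per_protein = pd.DataFrame(
        {
            "baseline": baseline,
            "trend": [trend_names[i] for i in trend_idx],
            "role": role,
            "side": side,
        },
        index=pd.Index(protein_ids, name="protein"),
    )
    per_timepoint = pd.DataFrame(
        {
            "protein": np.repeat(protein_ids, T),
            "gw": np.tile(gws, n),
            "true_log2_l": mu_l.ravel(),
            "true_log2_r": mu_r.ravel(),
            "label": labels.ravel(),
        }
    )
    return matrix, design, TruthTable(per_protein, per_timepoint)


def fixture_small(seed: int = 0) -> tuple[QuantMatrix, SampleDesign, TruthTable]:
    """A <=200-protein preset sized for unit tests.

    Guaranteed (by construction plus a deterministic seed sweep) to plant at
    least one protein of every truth label and to yield a non-empty core set.
    """
    base = dict(
        n_proteins=200,
        frac_aep=0.15,
        aep_log2_effect=2.0,
        frac_unilateral=0.10,
        noise_log2_sd=0.25,
        dropout_midpoint=18.0,
        dropout_slope=1.0,
    )
    for attempt in range(10):
        params = SimParams(seed=int(seed) + 10007 * attempt, **base)
        matrix, design, truth = generate(params)
        have = set(truth.per_timepoint["label"])
        core_ok = bool((matrix.intensities.to_numpy() > 0).all(axis=1).any())
        if set(LABELS) <= have and core_ok:
            return matrix, design, truth
    raise RuntimeError("fixture_small could not realize every truth label")


def designed(matrix: QuantMatrix, design: SampleDesign) -> DesignedMatrix:
    """Convenience: join the generated matrix with its design."""
    return join_design(matrix, design)
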