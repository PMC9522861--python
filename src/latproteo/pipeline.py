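"""End-to-end orchestration: core set -> DEP -> AEP/unilateral -> shared -> profiles -> PCA.

``run_all`` executes every stage in the order of the analysis narrative,
writes one TSV family per stage plus a JSON manifest, and logs the protein
count surviving each filter.  Analysis stages are deterministic; the single
seed governs only the synthetic generator, so identical config + seed yields
byte-identical numeric tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .asymmetry import asymmetry_records, shared_asymmetric
from .differential import call_deps, de_table, dep_summary, fit_models, moderate_variances
from .errors import ConfigurationError, PipelineError
from .preprocess import detection_sets, log2_normalize, overlap_counts, pca_summary, sample_correlation
from .profiles import run_profiles
from .quant_io import (
    SampleDesign,
    join_design,
    read_protein_groups,
    write_protein_groups,
    write_table,
)
from .synthetic_data import SimParams, generate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    outdir: str | Path
    matrix_path: str | None = None
    design_path: str | None = None
    synthetic: SimParams | None = None
    seed: int = 0
    fc_dep: float = 2.0
    fdr_dep: float = 0.05
    fc_aep: float = 2.0
    p_aep: float = 0.05
    floor_percentile: float = 1.0
    fc_shared: float = 1.5
    min_gws_shared: int = 2
    profile_c: int = 2
    profile_m: int = 16
    profile_alpha: float = 0.05

    def __post_init__(self):
        for name in ("fc_dep", "fdr_dep", "fc_aep", "p_aep", "floor_percentile",
                     "fc_shared", "profile_alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if self.synthetic is None and self.matrix_path is None:
            raise ConfigurationError("need either an input matrix or synthetic parameters")
        if self.matrix_path is not None and self.design_path is None:
            raise ConfigurationError("a file input needs a design table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        inp = raw.get("input", {})
        synth = None
        if "synthetic" in inp:
            synth = SimParams(**(inp["synthetic"] or {}))
        thresholds = raw.get("thresholds", {})
        return cls(
            outdir=raw.get("outdir", "latproteo_out"),
            matrix_path=inp.get("matrix"),
            design_path=inp.get("design"),
            synthetic=synth,
            seed=int(raw.get("seed", 0)),
            **thresholds,
        )


def _stage(name: str, outdir: Path):
    """Context manager marking a failed stage on disk before re-raising."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage: {name}\ncause: {exc}\n")
                raise PipelineError(name, exc)
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("latproteo")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "fc_dep", "fdr_dep", "fc_aep", "p_aep", "floor_percentile",
                "fc_shared", "min_gws_shared", "profile_c", "profile_m", "profile_alpha",
            )
        },
        "files": [],
        "counts": {},
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        write_table(frame, outdir / name)
        manifest["files"].append(name)

    try:
        with _stage("input", outdir):
            if config.synthetic is not None:
                params = config.synthetic
                params.seed = config.seed  # single seed governs all randomness
                matrix, design, truth = generate(params)
                emit("truth_per_timepoint.tsv", truth.per_timepoint)
                emit("truth_per_protein.tsv", truth.per_protein.reset_index())
            else:
                design = SampleDesign.read(config.design_path)
                matrix = read_protein_groups(config.matrix_path, samples=design.sample_ids)
            dm = join_design(matrix, design)
            write_protein_groups(matrix, outdir / "filtered_matrix.tsv")
            manifest["files"].append("filtered_matrix.tsv")
            design.write(outdir / "design.tsv")
            manifest["files"].append("design.tsv")
            manifest["counts"]["proteins_after_filtering"] = matrix.n_proteins
            log.info("input: %d proteins x %d samples", matrix.n_proteins, len(matrix.sample_ids))

        with _stage("detection", outdir):
            det = detection_sets(dm)
            emit("detection_counts.tsv", det.counts())
            bilateral_sets = {f"gw{gw}": det.bilateral[gw] for gw in dm.gws}
            emit("overlap_counts.tsv", overlap_counts(bilateral_sets))
            manifest["counts"]["core_set"] = len(det.core)
            log.info("core set: %d proteins", len(det.core))

        with _stage("differential", outdir):
            lm = log2_normalize(dm, det.core)
            fit = fit_models(lm, design)
            mod = moderate_variances(fit.s2, fit.df_resid)
            called = call_deps(de_table(fit, mod), config.fc_dep, config.fdr_dep)
            emit("dep_results.tsv", called)
            summary = dep_summary(called, len(det.core))
            emit("dep_summary.tsv", summary)
            manifest["counts"]["deps_per_interval"] = dict(
                zip(summary["interval"], summary["n_dep"].astype(int))
            )

        with _stage("asymmetry", outdir):
            records = {}
            for gw in dm.gws:
                rec = asymmetry_records(
                    dm, gw, config.fc_aep, config.p_aep, config.floor_percentile
                )
                records[gw] = rec
                emit(f"asymmetry_gw{gw}.tsv", rec)
                n_aep = int(rec["class"].isin(["aep_left", "aep_right"]).sum())
                n_uni = int(rec["class"].isin(["unilateral_left", "unilateral_right"]).sum())
                manifest["counts"][f"aep_gw{gw}"] = n_aep
                manifest["counts"][f"unilateral_gw{gw}"] = n_uni
                log.info("gw %d: %d AEPs, %d unilateral", gw, n_aep, n_uni)

        with _stage("shared_asymmetry", outdir):
            shared = shared_asymmetric(records, config.min_gws_shared, config.fc_shared)
            emit("shared_aeps.tsv", shared.shared)
            emit("shared_aep_pairs.tsv", shared.pairwise_counts)
            emit("shared_fold_consistent.tsv", shared.consistent_fold)
            manifest["counts"]["shared_aeps"] = int(len(shared.shared))
            manifest["counts"]["fold_consistent"] = int(len(shared.consistent_fold))

        with _stage("profiles", outdir):
            for side in ("L", "R"):
                ps = run_profiles(
                    lm, design, side, config.profile_c, config.profile_m, config.profile_alpha
                )
                emit(f"profiles_{side}.tsv", ps.table)
                emit(
                    f"profile_assignments_{side}.tsv",
                    ps.assignment.rename_axis("protein").reset_index(),
                )
                manifest["counts"][f"significant_profiles_{side}"] = int(
                    ps.table["significant"].sum()
                )

        with _stage("summaries", outdir):
            pca = pca_summary(lm)
            emit(
                "pca_variance.tsv",
                pd.DataFrame(
                    {
                        "pc": [f"PC{i + 1}" for i in range(len(pca.percent_variance))],
                        "percent_variance": pca.percent_variance,
                    }
                ),
            )
            emit("pca_scores.tsv", pca.sample_scores.rename_axis("sample").reset_index())
            emit(
                "sample_correlation.tsv",
                sample_correlation(lm).rename_axis("sample").reset_index(),
            )
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
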