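"""Reading and writing protein-group quantification tables.

The input dialect is the MaxQuant ``proteinGroups.txt`` convention: one row per
protein group, tab-separated, with per-sample ``LFQ intensity <sample>`` columns
and ``+``-style flag columns marking contaminants, reversed decoys and groups
identified only by modification site.  Flagged rows are removed on read; empty
intensity cells encode "not detected" and are stored as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DesignError

#: logical name -> default proteinGroups column
DEFAULT_COLUMNS: Mapping[str, str] = {
    "protein_ids": "Majority protein IDs",
    "gene_names": "Gene names",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "site_only": "Only identified by site",
    "intensity_prefix": "LFQ intensity ",
}

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class ProteinRecord:
    """Identity and flags of one protein group."""

    protein_group_id: str  # leading UniProt accession of the group
    gene_name: str = ""
    majority_ids: str = ""  # full semicolon-separated group string
    is_contaminant: bool = False
    is_reverse: bool = False
    is_site_only: bool = False

    @property
    def flagged(self) -> bool:
        return self.is_contaminant or self.is_reverse or self.is_site_only


@dataclass
class QuantMatrix:
    """Proteins x samples LFQ intensity matrix plus protein metadata.

    ``intensities`` is indexed by protein group id (leading accession) with one
    column per sample; zero means "not detected".  ``meta`` shares the index and
    carries ``gene_name`` and ``majority_ids``.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise DataError(f"duplicate protein group ids: {sorted(set(dups))[:5]}")
        if self.intensities.columns.has_duplicates:
            raise DataError("duplicate sample ids in intensity matrix")
        vals = self.intensities.to_numpy()
        if np.isnan(vals).any():
            raise DataError("NaN intensity; encode missing values as 0")
        if (vals < 0).any():
            bad = self.intensities.index[(vals < 0).any(axis=1)][0]
            raise DataError(f"negative intensity for protein {bad!r}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]


@dataclass
class SampleDesign:
    """Per-sample hemisphere (L/R) and gestational-week labels."""

    frame: pd.DataFrame  # index: sample id; columns: hemisphere, gw

    def __post_init__(self) -> None:
        required = {"hemisphere", "gw"}
        if not required.issubset(self.frame.columns):
            raise DesignError(f"design needs columns {sorted(required)}")
        if self.frame.index.has_duplicates:
            raise DesignError("duplicate sample ids in design")
        bad = set(self.frame["hemisphere"]) - set(HEMISPHERES)
        if bad:
            raise DesignError(f"hemisphere labels must be L or R, got {sorted(bad)}")
        pairs = list(zip(self.frame["hemisphere"], self.frame["gw"]))
        if len(pairs) != len(set(pairs)):
            raise DesignError("duplicated (hemisphere, gw) pair in design")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, int]]) -> "SampleDesign":
        frame = pd.DataFrame(
            {
                "hemisphere": [h for h, _ in mapping.values()],
                "gw": [int(g) for _, g in mapping.values()],
            },
            index=pd.Index(list(mapping), name="sample_id"),
        )
        return cls(frame)

    @classmethod
    def read(cls, path: str | Path) -> "SampleDesign":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in frame.columns:
            raise DesignError("design table needs a 'sample_id' column")
        return cls(frame.set_index("sample_id"))

    def write(self, path: str | Path) -> None:
        write_table(self.frame.reset_index(), path)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def gws(self) -> list[int]:
        return sorted(set(int(g) for g in self.frame["gw"]))

    def sample_for(self, hemisphere: str, gw: int) -> str:
        mask = (self.frame["hemisphere"] == hemisphere) & (self.frame["gw"] == gw)
        hits = self.frame.index[mask]
        if len(hits) != 1:
            raise DesignError(f"no unique sample for ({hemisphere}, gw {gw})")
        return str(hits[0])


@dataclass
class DesignedMatrix:
    """A QuantMatrix joined with a validated SampleDesign."""

    matrix: QuantMatrix
    design: SampleDesign

    @property
    def gws(self) -> list[int]:
        return self.design.gws

    @property
    def protein_ids(self) -> list[str]:
        return self.matrix.protein_ids

    def column(self, hemisphere: str, gw: int) -> pd.Series:
        """Intensity column for one (hemisphere, gw) cell."""
        return self.matrix.intensities[self.design.sample_for(hemisphere, gw)]

    def side_matrix(self, hemisphere: str) -> pd.DataFrame:
        """Intensities of one hemisphere, columns ordered by gw."""
        cols = [self.design.sample_for(hemisphere, gw) for gw in self.gws]
        out = self.matrix.intensities[cols].copy()
        out.columns = self.gws
        return out


def _is_flagged(series: pd.Series) -> pd.Series:
    """MaxQuant marks flags with '+'; treat any non-empty cell as flagged."""
    return series.fillna("").astype(str).str.strip() != ""


def read_protein_groups(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    samples: Sequence[str] | None = None,
) -> QuantMatrix:
    """Read a proteinGroups-dialect TSV into a :class:`QuantMatrix`.

    Rows flagged contaminant, reverse or site-only are removed; the remaining
    rows keep their file order.  ``samples`` restricts/orders the intensity
    columns; by default every ``LFQ intensity <sample>`` column is used.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str)

    if cols["protein_ids"] not in table.columns:
        raise ConfigurationError(f"missing required column {cols['protein_ids']!r}")
    prefix = cols["intensity_prefix"]
    intensity_cols = [c for c in table.columns if c.startswith(prefix)]
    if samples is not None:
        wanted = [prefix + s for s in samples]
        missing = [c for c in wanted if c not in table.columns]
        if missing:
            raise ConfigurationError(f"missing required column {missing[0]!r}")
        intensity_cols = wanted
    if not intensity_cols:
        raise ConfigurationError(f"no intensity columns with prefix {prefix!r}")

    keep = pd.Series(True, index=table.index)
    for flag in ("contaminant", "reverse", "site_only"):
        if cols[flag] in table.columns:
            keep &= ~_is_flagged(table[cols[flag]])
    table = table[keep]

    majority = table[cols["protein_ids"]].fillna("")
    lead = majority.str.split(";").str[0].str.strip()
    if (lead == "").any():
        raise DataError("empty protein group id")
    genes = (
        table[cols["gene_names"]].fillna("")
        if cols["gene_names"] in table.columns
        else pd.Series("", index=table.index)
    )

    intens = table[intensity_cols].apply(pd.to_numeric, errors="raise")
    intens = intens.fillna(0.0).astype(float)
    neg = (intens.to_numpy() < 0).any(axis=1)
    if neg.any():
        raise DataError(f"negative intensity for protein {lead[neg].iloc[0]!r}")

    intens.columns = [c[len(prefix):] for c in intensity_cols]
    intens.index = pd.Index(lead, name="protein_group_id")
    meta = pd.DataFrame(
        {"gene_name": genes.to_numpy(), "majority_ids": majority.to_numpy()},
        index=intens.index,
    )
    return QuantMatrix(intens, meta)


def to_protein_groups_frame(qm: QuantMatrix, intensity_prefix: str = "LFQ intensity ") -> pd.DataFrame:
    """Render a QuantMatrix back into the proteinGroups dialect."""
    out = pd.DataFrame(
        {
            "Majority protein IDs": qm.meta["majority_ids"].where(
                qm.meta["majority_ids"] != "", qm.meta.index
            ),
            "Gene names": qm.meta["gene_name"],
        },
        index=qm.intensities.index,
    )
    for s in qm.sample_ids:
        out[intensity_prefix + s] = qm.intensities[s]
    out["Potential contaminant"] = ""
    out["Reverse"] = ""
    out["Only identified by site"] = ""
    return out.reset_index(drop=True)


def write_protein_groups(qm: QuantMatrix, path: str | Path) -> None:
    write_table(to_protein_groups_frame(qm), path)


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a result table as UTF-8 TSV with one header row.

    Floats are written with pandas' shortest round-trip representation, so a
    write/read cycle reproduces values exactly.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    try:
        frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def join_design(matrix: QuantMatrix, design: SampleDesign) -> DesignedMatrix:
    """Attach a design to a matrix after checking sample ids match one-to-one."""
    m_ids, d_ids = set(matrix.sample_ids), set(design.sample_ids)
    missing_in_design = m_ids - d_ids
    if missing_in_design:
        raise DesignError(f"samples without design entry: {sorted(missing_in_design)}")
    missing_in_matrix = d_ids - m_ids
    if missing_in_matrix:
        raise DesignError(f"design sample absent from matrix: {sorted(missing_in_matrix)}")
    # every (hemisphere, gw) cell of the full grid must be present exactly once
    gws = design.gws
    missing_pairs = []
    for gw in gws:
        for h in HEMISPHERES:
            mask = (design.frame["hemisphere"] == h) & (design.frame["gw"] == gw)
            if mask.sum() != 1:
                missing_pairs.append((h, gw))
    if missing_pairs:
        raise DesignError(f"missing or duplicated (hemisphere, gw) cells: {missing_pairs}")
    return DesignedMatrix(matrix, design)
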