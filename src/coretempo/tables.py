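"""OTU count tables and their companions: metadata, taxonomy, and the
published per-subject core summary.

The central container is :class:`OtuTable`, an integer count matrix with
samples as rows and OTUs as columns.  All downstream analyses consume either
the raw counts or the percent-scale :class:`RelAbundanceTable` derived from
them.  Files are plain TSV (samples as rows in the canonical dialect, with an
orientation flag for transposed inputs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "SampleInfo",
    "CoreSummaryTable",
    "read_otu_table",
    "write_otu_table",
    "read_sample_info",
    "read_taxonomy",
    "read_core_summary",
    "load_table1",
    "filter_low_abundance",
    "to_relative",
]

RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU count matrix, samples x OTUs.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix indexed by sample id, with OTU ids as
        columns.  Sample order is meaningful and preserved by every
        transformation in this package.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            s, o = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[s]!r}, OTU {c.columns[o]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample read totals (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def select_samples(self, sample_ids: Iterable) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)])


@dataclass(frozen=True)
class RelAbundanceTable:
    """Relative abundances in percent of sample depth; rows sum to 100."""

    values: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)

    def select_samples(self, sample_ids: Iterable) -> "RelAbundanceTable":
        return RelAbundanceTable(self.values.loc[list(sample_ids)])


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata record."""

    sample_id: str
    subject: str
    week: int
    trial: int
    treatment: str
    chrono_index: int


@dataclass(frozen=True)
class CoreSummaryTable:
    """Published per-subject core summary: mean +/- SD relative abundance and
    percent of samples detected, per OTU and subject.

    ``stats`` has a row per OTU label and MultiIndex columns
    ``(subject, field)`` with fields ``mean``, ``sd``, ``pct_detected``; a
    subject in which the OTU was never detected ("ND") carries NaN in all
    three fields.
    """

    stats: pd.DataFrame
    phylum: pd.Series = field(repr=False)
    type_strain: pd.Series = field(repr=False)

    @property
    def otu_ids(self) -> list:
        return list(self.stats.index)

    @property
    def subjects(self) -> list:
        return list(self.stats.columns.get_level_values(0).unique())

    def subject_frame(self, subject: str) -> pd.DataFrame:
        """mean / sd / pct_detected for one subject (NaN where ND)."""
        return self.stats[subject]


# ---------------------------------------------------------------------------
# I/O


def _parse_numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    arr = df.to_numpy()
    bad = ~np.isfinite(pd.to_numeric(arr.ravel(), errors="coerce").reshape(arr.shape))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    num = df.apply(pd.to_numeric)
    frac = np.mod(num.to_numpy(), 1)
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise ValueError(
            f"{path}: non-integer count at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return num.astype(np.int64)


def read_otu_table(path, orientation: str = "samples-as-rows") -> OtuTable:
    """Read a TSV OTU table.

    ``orientation`` is ``"samples-as-rows"`` (canonical) or ``"otus-as-rows"``
    for transposed files; the result is always samples x OTUs.
    """
    if orientation not in ("samples-as-rows", "otus-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    num = _parse_numeric_frame(df, path)
    if orientation == "otus-as-rows":
        num = num.T
    num.index.name = None
    num.columns.name = None
    return OtuTable(num)


def write_otu_table(table: OtuTable, path) -> None:
    """Write in the canonical dialect: TSV, samples as rows, no quoting."""
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_info(path) -> list[SampleInfo]:
    """Read per-sample metadata (TSV with columns sample_id, subject, week,
    trial, treatment, chrono_index) and validate chronological ordering
    within each subject."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str})
    records = [
        SampleInfo(
            sample_id=str(r.sample_id),
            subject=str(r.subject),
            week=int(r.week),
            trial=int(r.trial),
            treatment=str(r.treatment),
            chrono_index=int(r.chrono_index),
        )
        for r in df.itertuples()
    ]
    for subject in {r.subject for r in records}:
        sub = sorted(
            (r for r in records if r.subject == subject), key=lambda r: r.chrono_index
        )
        weeks = [r.week for r in sub]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(
                f"weeks not strictly increasing with chrono_index for subject {subject}"
            )
    return records


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy map: TSV with otu_id plus rank columns
    (phylum..genus).  Empty cells mean unassigned at that rank; ranks must be
    filled left to right."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"taxonomy file lacks rank columns: {missing}")
    df = df[list(RANKS)]
    filled = df.notna()
    for coarse, fine in zip(RANKS, RANKS[1:]):
        bad = filled[fine] & ~filled[coarse]
        if bad.any():
            raise ValueError(
                f"OTU {df.index[bad.argmax()]!r} assigned at {fine} but not {coarse}"
            )
    return df


_CELL_RE = re.compile(r"^(\d+(?:\.\d+)?)±(\d+(?:\.\d+)?)\s*\((\d+(?:\.\d+)?)\)$")


def _parse_summary_cell(cell: str, row_label: str):
    cell = cell.strip()
    if cell == "ND":
        return (np.nan, np.nan, np.nan)
    m = _CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"malformed summary cell for OTU {row_label!r}: {cell!r}")
    return tuple(float(g) for g in m.groups())


def read_core_summary(path) -> CoreSummaryTable:
    """Parse a published-core summary TSV whose per-subject cells are
    formatted ``mean±sd (pct_detected)`` or ``ND``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    subjects = [c for c in df.columns if c not in ("phylum", "type_strain")]
    cols = {}
    for subj in subjects:
        parsed = [_parse_summary_cell(c, i) for i, c in df[subj].items()]
        sub = pd.DataFrame(
            parsed, index=df.index, columns=["mean", "sd", "pct_detected"]
        )
        name = subj.removeprefix("subject_")
        cols[name] = sub
    stats = pd.concat(cols, axis=1)
    pct = stats.xs("pct_detected", axis=1, level=1)
    if ((pct < 0) | (pct > 100)).any().any():
        raise ValueError("pct_detected outside [0, 100]")
    return CoreSummaryTable(
        stats=stats,
        phylum=df["phylum"].astype(str),
        type_strain=df["type_strain"].astype(str),
    )


def load_table1() -> CoreSummaryTable:
    """Load the packaged 69-OTU published core summary fixture."""
    ref = resources.files("coretempo.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return read_core_summary(path)


# ---------------------------------------------------------------------------
# Transforms


def filter_low_abundance(
    table: OtuTable,
    groups: Mapping[str, str],
    min_count: int = 5,
    per_subject: bool = False,
) -> OtuTable:
    """Drop very low abundance OTUs.

    An OTU is removed from the whole table only when its summed count is
    <= ``min_count`` within *every* subject, so an OTU well represented in one
    subject is kept everywhere (shared-OTU analyses need consistent columns).
    With ``per_subject=True`` the rule is instead applied within each subject:
    counts are zeroed in subjects where the subject sum is <= ``min_count``,
    and OTUs left with no reads anywhere are dropped.

    ``groups`` maps every sample id to its subject.
    """
    unmapped = [s for s in table.sample_ids if s not in groups]
    if unmapped:
        raise ValueError(f"samples not mapped to a subject: {unmapped}")
    subj = pd.Series({s: groups[s] for s in table.sample_ids})
    sums = table.counts.groupby(subj, sort=False).sum()  # subjects x OTUs
    if per_subject:
        keep_mask = sums > min_count  # subjects x OTUs
        expanded = keep_mask.loc[subj.values].set_axis(table.counts.index)
        filtered = table.counts.where(expanded, 0)
        filtered = filtered.loc[:, filtered.sum(axis=0) > 0]
        return OtuTable(filtered)
    keep = sums.columns[(sums > min_count).any(axis=0)]
    return OtuTable(table.counts[keep])


def to_relative(table: OtuTable) -> RelAbundanceTable:
    """Convert counts to percent of per-sample depth."""
    depths = table.depths
    zero = depths[depths == 0]
    if len(zero):
        raise ValueError(f"zero-depth samples: {list(zero.index)}")
    return RelAbundanceTable(100.0 * table.counts.div(depths, axis=0))
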