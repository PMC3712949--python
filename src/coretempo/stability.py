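"""Taxonomic-rank stability and phylum-ratio dynamics.

Gut communities look far more stable at coarse taxonomic scales than at the
species (OTU) level: collapsing a count table from OTUs up to genus, family,
order, class or phylum merges presence/absence patterns, so any set-overlap
statistic can only improve.  This module quantifies that with mean pairwise
Jaccard similarity of presence sets per rank, and tracks the
Firmicutes:Bacteroidetes abundance ratio over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import RANKS, OtuTable, RelAbundanceTable

__all__ = [
    "RankStabilityProfile",
    "collapse_to_rank",
    "rank_stability",
    "fb_ratio",
    "summarize_ratio",
]


@dataclass(frozen=True)
class RankStabilityProfile:
    """Mean pairwise Jaccard similarity of presence sets per taxonomic rank,
    ordered coarse (phylum) to fine (otu)."""

    subject: str
    values: "dict[str, float]"  # rank -> similarity in [0, 1]


def _rank_labels(taxonomy: pd.DataFrame, otu_ids: Sequence, rank: str) -> pd.Series:
    """Label per OTU at ``rank``; OTUs unassigned at that rank pool into
    ``unclassified-<nearest assigned parent>`` so no reads are dropped."""
    idx = RANKS.index(rank)
    labels = {}
    for otu in otu_ids:
        if otu in taxonomy.index:
            lineage = taxonomy.loc[otu, list(RANKS[: idx + 1])]
            if pd.notna(lineage.iloc[-1]):
                labels[otu] = str(lineage.iloc[-1])
                continue
            parents = lineage.dropna()
            parent = str(parents.iloc[-1]) if len(parents) else "root"
        else:
            parent = "root"
        labels[otu] = f"unclassified-{parent}"
    return pd.Series(labels)


def collapse_to_rank(
    table: OtuTable, taxonomy: pd.DataFrame, rank: str
) -> OtuTable:
    """Sum counts over OTUs sharing a taxon label at ``rank``.

    Per-sample depth is conserved exactly: OTUs without an assignment at the
    requested rank are pooled under an ``unclassified-<parent>`` label rather
    than discarded.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}: {rank!r}")
    labels = _rank_labels(taxonomy, table.otu_ids, rank)
    collapsed = table.counts.T.groupby(labels, sort=True).sum().T
    return OtuTable(collapsed)


def _mean_pairwise_jaccard(present: np.ndarray, consecutive: bool) -> float:
    n = present.shape[0]
    pairs = (
        [(i, i + 1) for i in range(n - 1)]
        if consecutive
        else list(combinations(range(n), 2))
    )
    sims = []
    for i, j in pairs:
        inter = np.logical_and(present[i], present[j]).sum()
        union = np.logical_or(present[i], present[j]).sum()
        sims.append(1.0 if union == 0 else inter / union)
    return float(np.mean(sims))


def rank_stability(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    samples: Sequence,
    subject: str = "",
    consecutive: bool = False,
) -> RankStabilityProfile:
    """Presence/absence stability of one subject's series at every rank.

    For each rank (phylum down to genus, plus the uncollapsed OTU level) the
    statistic is the mean Jaccard similarity of presence sets over all sample
    pairs, or over consecutive pairs only with ``consecutive=True``.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    values = {}
    for rank in RANKS:
        sub = collapse_to_rank(table, taxonomy, rank).select_samples(samples)
        values[rank] = _mean_pairwise_jaccard(sub.counts.to_numpy() >= 1, consecutive)
    sub = table.select_samples(samples)
    values["otu"] = _mean_pairwise_jaccard(sub.counts.to_numpy() >= 1, consecutive)
    return RankStabilityProfile(subject=subject, values=values)


def fb_ratio(rel: RelAbundanceTable, taxonomy: pd.DataFrame) -> pd.Series:
    """Per-sample Firmicutes:Bacteroidetes relative-abundance ratio.

    Samples with no Bacteroidetes reads get ``inf`` (flagged with a warning);
    use :func:`summarize_ratio` for finite-only period summaries.
    """
    phyla = taxonomy["phylum"]
    for needed in ("Firmicutes", "Bacteroidetes"):
        if needed not in set(phyla.dropna()):
            raise ValueError(f"taxonomy contains no {needed} OTUs")
    cols = rel.values.columns
    f_cols = [c for c in cols if phyla.get(c) == "Firmicutes"]
    b_cols = [c for c in cols if phyla.get(c) == "Bacteroidetes"]
    f = rel.values[f_cols].sum(axis=1)
    b = rel.values[b_cols].sum(axis=1)
    with np.errstate(divide="ignore"):
        ratio = f / b
    if np.isinf(ratio).any():
        warnings.warn(
            f"{int(np.isinf(ratio).sum())} sample(s) with zero Bacteroidetes; "
            "ratio reported as inf and excluded from summaries",
            stacklevel=2,
        )
    ratio.name = "fb_ratio"
    return ratio


def summarize_ratio(
    ratio: pd.Series, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Mean +/- SD of a per-sample ratio within sample groups (e.g. trial
    periods), excluding infinite values."""
    grp = pd.Series({s: groups[s] for s in ratio.index})
    finite = ratio[np.isfinite(ratio)]
    out = finite.groupby(grp.loc[finite.index]).agg(["mean", "std", "count"])
    out.columns = ["mean", "sd", "n"]
    return out
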