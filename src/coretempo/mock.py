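"""Defined-community (mock) validation of OTU-based diversity measures.

Sequencing a community of known membership exposes how much observed OTU
richness is artifactual: errors spawn spurious OTUs, inflating per-sample
and total richness and shrinking the apparent shared fraction, while the
handful of OTUs detected in every sample still carry nearly all the reads.
:func:`evaluate_mock` condenses a mock run into those diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import OtuTable

__all__ = ["MockReport", "evaluate_mock", "genus_composition", "subsample"]


@dataclass(frozen=True)
class MockReport:
    """Diversity-inflation diagnostics for a defined community run."""

    expected_taxa: tuple
    observed_total_otus: int
    observed_total_otus_filtered: int  # OTUs with > min_count reads overall
    mean_otus_per_sample: float
    shared_all_samples: frozenset
    shared_otu_fraction: float  # percent of total OTUs detected in all samples
    shared_seq_fraction: float  # percent of reads in the shared set
    top_k_seq_fraction: float  # percent of reads in the k most abundant OTUs
    genus_fractions: "dict[str, float]"  # observed percent per expected genus
    inflation_factor: float  # observed_total_otus / len(expected_taxa)


def genus_composition(table: OtuTable, taxonomy: pd.DataFrame) -> pd.Series:
    """Percent of pooled reads per genus; OTUs without a genus assignment
    pool under ``unclassified``.  Fractions sum to 100."""
    totals = table.counts.sum(axis=0)
    genus = pd.Series(
        {
            o: (
                str(taxonomy.loc[o, "genus"])
                if o in taxonomy.index and pd.notna(taxonomy.loc[o, "genus"])
                else "unclassified"
            )
            for o in table.otu_ids
        }
    )
    pooled = totals.groupby(genus).sum()
    return 100.0 * pooled / pooled.sum()


def evaluate_mock(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    expected: Sequence[str],
    min_count: int = 5,
) -> MockReport:
    """Summarize observed diversity against a known community.

    ``expected`` lists the genera actually inoculated.  The shared set is
    every OTU with a count >= 1 in all samples; top-k uses k = number of
    expected taxa, ranked by total reads.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not expected:
        raise ValueError("expected taxon list is empty")
    counts = table.counts
    detected = counts >= 1
    observed = detected.any(axis=0)
    total_otus = int(observed.sum())
    totals = counts.sum(axis=0)
    filtered = int((totals > min_count).sum())
    per_sample = detected.sum(axis=1)
    shared = frozenset(counts.columns[detected.all(axis=0)])
    grand_total = int(totals.sum())
    shared_seq = 100.0 * totals[list(shared)].sum() / grand_total if shared else 0.0
    k = len(expected)
    top_k = totals.sort_values(ascending=False, kind="stable").index[:k]
    top_k_seq = 100.0 * totals[top_k].sum() / grand_total
    comp = genus_composition(table, taxonomy)
    genus_fractions = {}
    for genus in expected:
        if genus in comp.index:
            genus_fractions[genus] = float(comp[genus])
        else:
            warnings.warn(f"expected genus {genus!r} not observed", stacklevel=2)
            genus_fractions[genus] = 0.0
    return MockReport(
        expected_taxa=tuple(expected),
        observed_total_otus=total_otus,
        observed_total_otus_filtered=filtered,
        mean_otus_per_sample=float(per_sample.mean()),
        shared_all_samples=shared,
        shared_otu_fraction=100.0 * len(shared) / total_otus,
        shared_seq_fraction=float(shared_seq),
        top_k_seq_fraction=float(top_k_seq),
        genus_fractions=genus_fractions,
        inflation_factor=total_otus / k,
    )


def subsample(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Randomly subsample each sample to a fixed depth without replacement
    (multivariate hypergeometric draw, seeded)."""
    rng = np.random.default_rng(seed)
    rows = {}
    for s in table.sample_ids:
        row = table.counts.loc[s].to_numpy()
        if row.sum() < depth:
            raise ValueError(f"sample {s!r} has fewer than {depth} reads")
        rows[s] = rng.multivariate_hypergeometric(row, depth)
    sub = pd.DataFrame.from_dict(rows, orient="index", columns=table.counts.columns)
    return OtuTable(sub.loc[table.sample_ids])
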