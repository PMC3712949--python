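"""Temporal-core detection and quantification.

A subject's temporal core is the set of OTUs detected (at least one read) in
at least a threshold percentage of that subject's longitudinal samples
(default 80%, inclusive).  Although such persistent OTUs are typically a
small fraction of the observed richness, they carry most of the sequenced
reads — the quantities computed here make that dominance explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import CoreSummaryTable, OtuTable, RelAbundanceTable, to_relative

__all__ = [
    "CoreSet",
    "SharedCurve",
    "detect_core",
    "core_abundance_fraction",
    "shared_core",
    "summary_core_counts",
    "accumulated_shared_curve",
    "per_phylum_core_fraction",
]


@dataclass(frozen=True)
class CoreSet:
    """Persistent OTUs of one subject at a given prevalence threshold.

    ``prevalence`` and ``mean_abundance`` (percent scales) are indexed by
    member OTU; ``samples`` records the sample ids the core was called on.
    """

    subject: str
    threshold: float
    members: frozenset
    prevalence: pd.Series
    mean_abundance: pd.Series
    samples: tuple


@dataclass(frozen=True)
class SharedCurve:
    """Accumulated shared-OTU curve over an ordered sample series.

    At each k, ``shared_otus[k-1]`` is the set of OTUs present in all of the
    first k samples; ``otu_fraction`` is its share of the OTUs observed so
    far and ``seq_fraction`` the share of reads so far that those shared
    OTUs carry (both percent).
    """

    k: np.ndarray
    shared_otus: tuple
    otu_fraction: np.ndarray
    seq_fraction: np.ndarray


def detect_core(
    table: OtuTable, samples: Sequence, threshold: float = 80.0, subject: str = ""
) -> CoreSet:
    """Call the temporal core of one subject.

    An OTU is a member iff it has a count >= 1 in at least ``threshold``
    percent of ``samples`` (inclusive comparison, no rounding of the ratio).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100]: {threshold}")
    sub = table.select_samples(samples)
    prevalence = 100.0 * (sub.counts >= 1).mean(axis=0)
    members = prevalence.index[prevalence >= threshold]
    rel = to_relative(sub)
    mean_ab = rel.values[members].mean(axis=0)
    return CoreSet(
        subject=subject,
        threshold=float(threshold),
        members=frozenset(members),
        prevalence=prevalence[members],
        mean_abundance=mean_ab,
        samples=tuple(samples),
    )


def core_abundance_fraction(
    core: CoreSet, data: RelAbundanceTable | CoreSummaryTable
) -> float:
    """Percent of a subject's reads belonging to core members.

    For a :class:`RelAbundanceTable` this is the mean over the core's samples
    of the summed member proportions.  For a published summary table it is
    the sum of the printed per-OTU means for the core's subject.
    """
    members = sorted(core.members, key=str)
    if isinstance(data, CoreSummaryTable):
        frame = data.subject_frame(core.subject)
        missing = [m for m in members if m not in frame.index]
        if missing:
            raise KeyError(f"core members absent from summary table: {missing}")
        return float(frame.loc[members, "mean"].sum())
    missing = [m for m in members if m not in data.values.columns]
    if missing:
        raise KeyError(f"core members absent from table: {missing}")
    rows = data.values.loc[list(core.samples), members]
    return float(rows.sum(axis=1).mean())


def shared_core(cores: Iterable[CoreSet]) -> frozenset:
    """OTUs persistent in every subject: intersection of member sets."""
    cores = list(cores)
    if len(cores) < 2:
        raise ValueError("need at least two cores to intersect")
    out = frozenset(cores[0].members)
    for c in cores[1:]:
        out &= c.members
    return out


def summary_core_counts(
    summary: CoreSummaryTable, threshold: float = 80.0
) -> pd.DataFrame:
    """Per-subject core statistics from a published summary table.

    Returns a frame indexed by subject with columns ``n_core`` (rows whose
    printed detection percentage meets ``threshold``), ``core_abundance_sum``
    (sum of those rows' printed means) and ``total_abundance_sum`` (sum of
    all non-ND means, the printed column totals).
    """
    rows = []
    for subj in summary.subjects:
        frame = summary.subject_frame(subj)
        in_core = frame["pct_detected"] >= threshold
        rows.append(
            {
                "subject": subj,
                "n_core": int(in_core.sum()),
                "core_abundance_sum": float(frame.loc[in_core, "mean"].sum()),
                "total_abundance_sum": float(frame["mean"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("subject")


def summary_cores(summary: CoreSummaryTable, threshold: float = 80.0) -> list[CoreSet]:
    """Build per-subject :class:`CoreSet` objects from a published summary,
    taking the printed detection percentage as the prevalence."""
    out = []
    for subj in summary.subjects:
        frame = summary.subject_frame(subj)
        in_core = frame["pct_detected"] >= threshold
        members = frame.index[in_core]
        out.append(
            CoreSet(
                subject=subj,
                threshold=float(threshold),
                members=frozenset(members),
                prevalence=frame.loc[members, "pct_detected"],
                mean_abundance=frame.loc[members, "mean"],
                samples=(),
            )
        )
    return out


def accumulated_shared_curve(
    table: OtuTable,
    order: Sequence | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> SharedCurve:
    """Shared-OTU accumulation curve over an ordered sample series.

    With ``order`` given (default: the table's stored sample order) the curve
    follows that — normally chronological — ordering.  With
    ``n_permutations`` > 0 the OTU- and sequence-fractions are instead
    averaged over that many random sample orderings (seeded); the shared sets
    reported then come from the stored order.
    """
    samples = list(order) if order is not None else table.sample_ids
    if sorted(map(str, samples)) != sorted(map(str, table.sample_ids)):
        raise ValueError("order must be a permutation of the table's samples")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        base = _curve_arrays(table, samples)
        otu_acc = np.zeros(len(samples))
        seq_acc = np.zeros(len(samples))
        for _ in range(n_permutations):
            perm = [samples[i] for i in rng.permutation(len(samples))]
            _, of, sf = _curve_arrays(table, perm)
            otu_acc += of
            seq_acc += sf
        shared, _, _ = base
        return SharedCurve(
            k=np.arange(1, len(samples) + 1),
            shared_otus=shared,
            otu_fraction=otu_acc / n_permutations,
            seq_fraction=seq_acc / n_permutations,
        )
    shared, of, sf = _curve_arrays(table, samples)
    return SharedCurve(
        k=np.arange(1, len(samples) + 1),
        shared_otus=shared,
        otu_fraction=of,
        seq_fraction=sf,
    )


def _curve_arrays(table: OtuTable, samples: list):
    counts = table.counts.loc[samples]
    present = counts.to_numpy() >= 1
    n = len(samples)
    shared_sets = []
    otu_fraction = np.empty(n)
    seq_fraction = np.empty(n)
    shared = present[0].copy()
    union = present[0].copy()
    cum = np.zeros(counts.shape[1], dtype=np.int64)
    for k in range(n):
        if k:
            shared &= present[k]
            union |= present[k]
        cum += counts.to_numpy()[k]
        shared_sets.append(frozenset(counts.columns[shared]))
        otu_fraction[k] = 100.0 * shared.sum() / union.sum()
        seq_fraction[k] = 100.0 * cum[shared].sum() / cum.sum()
    return tuple(shared_sets), otu_fraction, seq_fraction


def per_phylum_core_fraction(
    core: CoreSet, rel: RelAbundanceTable, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample percent of reads in core OTUs, split by phylum.

    Returns samples x phyla; summing across phyla recovers each sample's
    total core fraction.  Every core member must carry a phylum assignment.
    """
    members = sorted(core.members, key=str)
    known = taxonomy["phylum"].dropna()
    unassigned = [m for m in members if m not in known.index]
    if unassigned:
        raise ValueError(f"core members without phylum assignment: {unassigned}")
    rows = rel.values.loc[list(core.samples), members]
    phyla = known.loc[members]
    return rows.T.groupby(phyla, sort=True).sum().T
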