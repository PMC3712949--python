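"""Merging of over-split OTUs by representative-sequence similarity.

OTU pickers routinely split one 16S phylotype into several clusters.  This
module re-joins persistent OTUs whose representative amplicon sequences are
more than ``cutoff`` percent identical (strictly greater; the 97.0 boundary
does not merge), using single-linkage: any chain of above-cutoff pairs ends
up in one group.  Identity is computed on a global pairwise alignment as
matches over aligned columns, excluding terminal-gap columns so that
amplicons trimmed to different lengths are not penalized — the complement of
the p-distance on the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AlignScoring",
    "RepSeqSet",
    "MergeResult",
    "read_rep_seqs",
    "pairwise_similarity",
    "merge_otus",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class AlignScoring:
    """Global-alignment scores: a gap run of length L costs
    ``open + extend * (L - 1)``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class RepSeqSet:
    """Representative nucleotide sequences per OTU, with phylum labels."""

    sequences: Mapping[str, str]
    phylum: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for OTU {otu!r}")
            bad = set(seq.upper()) - _IUPAC
            if bad:
                raise ValueError(f"invalid characters in OTU {otu!r}: {sorted(bad)}")


@dataclass(frozen=True)
class MergeResult:
    """Partition of OTUs into merged groups.

    ``groups`` maps each group's representative (its most abundant member,
    ties to the lexicographically smallest id) to the sorted member list;
    ``group_of`` maps every input OTU to its representative;
    ``similarity`` is the pairwise percent-identity matrix used.
    """

    groups: "dict[str, list[str]]"
    group_of: "dict[str, str]"
    group_abundance: "dict[str, float]"
    similarity: pd.DataFrame


def read_rep_seqs(path, phylum: Mapping[str, str] | None = None) -> RepSeqSet:
    """Read representative sequences from FASTA (record id = OTU id)."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate OTU id in FASTA: {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return RepSeqSet(sequences=seqs, phylum=dict(phylum or {}))


def _aligner(scoring: AlignScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def pairwise_similarity(
    a: str, b: str, scoring: AlignScoring = AlignScoring()
) -> float:
    """Percent identity of two sequences on their global alignment.

    Identity counts matching columns over all aligned columns except those
    under a terminal gap (a leading or trailing gap run in either row).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    alignment = _aligner(scoring).align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return _identity_from_rows(row_a, row_b)


def _identity_from_rows(row_a: str, row_b: str) -> float:
    n = len(row_a)
    start, end = 0, n
    for row in (row_a, row_b):
        lead = len(row) - len(row.lstrip("-"))
        trail = len(row) - len(row.rstrip("-"))
        start = max(start, lead)
        end = min(end, n - trail)
    if end <= start:
        raise ValueError("alignment has no non-terminal columns")
    matches = sum(row_a[i] == row_b[i] for i in range(start, end))
    return 100.0 * matches / (end - start)


def merge_otus(
    seqs: RepSeqSet,
    abundances: Mapping[str, float],
    cutoff: float = 97.0,
    within_phylum: bool = True,
    scoring: AlignScoring = AlignScoring(),
) -> MergeResult:
    """Single-linkage merge of OTUs whose similarity exceeds ``cutoff``.

    Edges exist at similarity strictly greater than ``cutoff``; with
    ``within_phylum`` only same-phylum pairs may join.  Group abundance is
    the sum over members; the representative is the highest-abundance member
    (ties to the smallest id).
    """
    otus = sorted(seqs.sequences)
    missing = [o for o in otus if o not in abundances]
    if missing:
        raise ValueError(f"missing abundances for OTUs: {missing}")
    n = len(otus)
    sim = np.full((n, n), 100.0)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_similarity(
                seqs.sequences[otus[i]], seqs.sequences[otus[j]], scoring
            )
            sim[i, j] = sim[j, i] = s
            same_phylum = (not within_phylum) or (
                seqs.phylum.get(otus[i]) == seqs.phylum.get(otus[j])
            )
            adj[i, j] = adj[j, i] = s > cutoff and same_phylum
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[str, list[str]] = {}
    group_of: dict[str, str] = {}
    group_abundance: dict[str, float] = {}
    for comp in range(n_comp):
        members = sorted(np.asarray(otus, dtype=object)[labels == comp])
        rep = min(members, key=lambda o: (-abundances[o], str(o)))
        groups[rep] = members
        group_abundance[rep] = float(sum(abundances[o] for o in members))
        for o in members:
            group_of[o] = rep
    return MergeResult(
        groups=groups,
        group_of=group_of,
        group_abundance=group_abundance,
        similarity=pd.DataFrame(sim, index=otus, columns=otus),
    )
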