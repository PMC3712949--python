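"""Sequence-similarity computation and single-linkage OTU merging."""

import numpy as np
import pytest

from coretempo import AlignScoring, RepSeqSet, merge_otus, pairwise_similarity
from coretempo.merge import _aligner, _identity_from_rows


def gotoh_score(a, b, match=1.0, mismatch=-1.0, open_=-5.0, extend=-2.0):
    """Independent affine-gap global alignment score by dynamic programming
    (a gap run of length L costs open_ + extend * (L - 1))."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = open_ + extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend,
                          Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend,
                          X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT")) for _ in range(length))


def mutate(rng, seq, n_sub=0, n_indel=0):
    s = list(seq)
    for i in rng.choice(len(s), size=n_sub, replace=False):
        s[i] = rng.choice([c for c in "ACGT" if c != s[i]])
    for _ in range(n_indel):
        pos = rng.integers(1, len(s) - 1)
        if rng.random() < 0.5:
            s.insert(pos, rng.choice(list("ACGT")))
        else:
            del s[pos]
    return "".join(s)


class TestPairwiseSimilarity:
    def test_identical_sequences_are_100(self, rng):
        seq = random_seq(rng, 400)
        assert pairwise_similarity(seq, seq) == 100.0

    def test_three_substitutions_in_100nt_give_97(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, n_sub=3)
        assert pairwise_similarity(a, b) == pytest.approx(97.0)

    def test_alignment_score_matches_dp_oracle(self, rng):
        for _ in range(15):
            a = random_seq(rng, int(rng.integers(20, 61)))
            b = mutate(rng, a, n_sub=int(rng.integers(0, 4)),
                       n_indel=int(rng.integers(0, 3)))
            aln = _aligner(AlignScoring()).align(a, b)[0]
            assert aln.score == pytest.approx(gotoh_score(a, b))
            # identity recomputed column-by-column from the emitted rows
            row_a, row_b = str(aln[0]), str(aln[1])
            assert pairwise_similarity(a, b) == pytest.approx(
                _identity_from_rows(row_a, row_b)
            )

    def test_terminal_gaps_do_not_dilute_identity(self):
        # identical amplicons trimmed to different lengths
        assert _identity_from_rows("ACGTACGT", "ACGTAC--") == 100.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_similarity("", "ACGT")


def _seqs_with_similarity(rng):
    """A=B=98%, B~C=98%, A~C=96% style chain on 100-nt sequences."""
    a = random_seq(rng, 100)
    b = mutate(rng, a, n_sub=2)   # 98 vs a
    c = mutate(rng, b, n_sub=2)   # 98 vs b, ~96 vs a
    return a, b, c


class TestMergeOtus:
    def test_chain_rule_joins_transitively(self, rng):
        a, b, c = _seqs_with_similarity(rng)
        assert pairwise_similarity(a, c) < 97.5  # chain, not a direct edge
        seqs = RepSeqSet({"A": a, "B": b, "C": c},
                         {"A": "F", "B": "F", "C": "F"})
        result = merge_otus(seqs, {"A": 1.0, "B": 5.0, "C": 2.0})
        assert result.groups == {"B": ["A", "B", "C"]}
        assert result.group_abundance["B"] == pytest.approx(8.0)

    def test_below_cutoff_pairs_never_merge(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, n_sub=5)  # 95%
        seqs = RepSeqSet({"A": a, "B": b}, {"A": "F", "B": "F"})
        result = merge_otus(seqs, {"A": 1.0, "B": 1.0})
        assert set(result.groups) == {"A", "B"}

    def test_exact_97_boundary_does_not_merge(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, n_sub=3)  # exactly 97.0
        seqs = RepSeqSet({"A": a, "B": b}, {"A": "F", "B": "F"})
        assert pairwise_similarity(a, b) == pytest.approx(97.0)
        result = merge_otus(seqs, {"A": 1.0, "B": 1.0})
        assert set(result.groups) == {"A", "B"}

    def test_within_phylum_blocks_cross_phylum_edges(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, n_sub=1)
        seqs = RepSeqSet({"A": a, "B": b}, {"A": "F", "B": "Bact"})
        assert set(merge_otus(seqs, {"A": 1, "B": 1}).groups) == {"A", "B"}
        assert set(merge_otus(seqs, {"A": 1, "B": 1}, within_phylum=False).groups) == {"A"}

    def test_partition_matches_union_find_oracle(self, rng):
        for trial in range(3):
            base = random_seq(rng, 80)
            names = [f"o{i}" for i in range(8)]
            seqs = {
                n: mutate(rng, base, n_sub=int(rng.integers(0, 6))) for n in names
            }
            rep_set = RepSeqSet(seqs, {n: "F" for n in names})
            ab = {n: float(i + 1) for i, n in enumerate(names)}
            result = merge_otus(rep_set, ab)
            # union-find over the thresholded similarity matrix
            parent = {n: n for n in names}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, n1 in enumerate(names):
                for n2 in names[i + 1 :]:
                    if result.similarity.loc[n1, n2] > 97.0:
                        parent[find(n1)] = find(n2)
            expected = {}
            for n in names:
                expected.setdefault(find(n), set()).add(n)
            got = {frozenset(m) for m in result.groups.values()}
            assert got == {frozenset(m) for m in expected.values()}

    def test_merging_representatives_is_idempotent(self, rng):
        a, b, c = _seqs_with_similarity(rng)
        d = random_seq(rng, 100)
        seqs = RepSeqSet(
            {"A": a, "B": b, "C": c, "D": d},
            {k: "F" for k in "ABCD"},
        )
        ab = {"A": 4.0, "B": 1.0, "C": 2.0, "D": 3.0}
        first = merge_otus(seqs, ab)
        reps = RepSeqSet(
            {r: seqs.sequences[r] for r in first.groups},
            {r: "F" for r in first.groups},
        )
        second = merge_otus(reps, first.group_abundance)
        assert all(members == [rep] for rep, members in second.groups.items())

    def test_abundance_conserved_and_cutoff_monotone(self, rng):
        base = random_seq(rng, 90)
        names = [f"o{i}" for i in range(6)]
        seqs = RepSeqSet(
            {n: mutate(rng, base, n_sub=int(rng.integers(0, 5))) for n in names},
            {n: "F" for n in names},
        )
        ab = {n: float(i + 1) for i, n in enumerate(names)}
        coarse = merge_otus(seqs, ab, cutoff=95.0)
        fine = merge_otus(seqs, ab, cutoff=98.0)
        assert sum(coarse.group_abundance.values()) == pytest.approx(sum(ab.values()))
        assert sum(fine.group_abundance.values()) == pytest.approx(sum(ab.values()))
        # raising the cutoff refines the partition
        for members in fine.groups.values():
            reps = {coarse.group_of[m] for m in members}
            assert len(reps) == 1

    def test_missing_abundance_errors(self, rng):
        seqs = RepSeqSet({"A": random_seq(rng, 50)}, {"A": "F"})
        with pytest.raises(ValueError, match="missing"):
            merge_otus(seqs, {})
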