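"""Alignment engine: pairwise DP vs brute force, guide tree, progressive MSA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domainhotspots.errors import ValidationError
from domainhotspots.families import DomainFamily, DomainInstance
from domainhotspots.io import AA_ALPHABET, write_aligned_fasta
from domainhotspots.msa import (GuideTree, Profile, SubstitutionMatrix,
                                align_profiles, blosum80, build_guide_tree,
                                kmer_distance, load_external_alignment,
                                pairwise_global_align, progressive_align)


def brute_force_score(a, b, matrix, go, ge):
    """Independent oracle: enumerate every global alignment recursively.

    A maximal gap run of length ℓ costs go + ℓ·ge; match columns score via
    the substitution matrix. No dynamic programming, no pruning.
    """
    best = -math.inf

    def rec(i, j, last, acc):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "D", acc + matrix.score(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "U", acc - ge - (go if last != "U" else 0))
        if j < len(b):
            rec(i, j + 1, "L", acc - ge - (go if last != "L" else 0))

    rec(0, 0, None, 0.0)
    return best


def make_family(seqs, acc="PF1"):
    instances = []
    for i, s in enumerate(seqs):
        instances.append(DomainInstance(
            instance_id=f"P{i}:1-{len(s)}", domain_acc=acc, domain_name="D",
            protein_id=f"P{i}", gene=f"G{i}", start=1, end=len(s),
            e_value=1e-12, sequence=s))
    return DomainFamily(acc, "D", instances)


class TestSubstitutionMatrix:
    def test_blosum80_is_symmetric_and_complete(self):
        m = blosum80()
        assert m.scores.shape == (20, 20)
        assert np.array_equal(m.scores, m.scores.T)
        # NCBI BLOSUM80 (1/3-bit scale) diagonal spot checks
        assert m.score("W", "W") == 16
        assert m.score("A", "A") == 7

    def test_nonstandard_residue_scores_matrix_minimum(self):
        m = blosum80()
        worst = m.scores.min()
        assert m.score("X", "A") == worst
        assert m.score("A", "B") == worst

    def test_asymmetric_matrix_rejected(self):
        bad = np.zeros((20, 20))
        bad[0, 1] = 1.0
        with pytest.raises(ValidationError, match="symmetric"):
            SubstitutionMatrix(AA_ALPHABET, bad)


class TestPairwiseAlign:
    def test_identical_sequences_align_on_diagonal(self):
        m = blosum80()
        score, (a, b) = pairwise_global_align("ACD", "ACD", m)
        assert a == b == "ACD"
        assert score == m.score("A", "A") + m.score("C", "C") + m.score("D", "D")

    def test_empty_side_costs_one_affine_gap(self):
        score, (a, b) = pairwise_global_align("AA", "", gap_open=10, gap_extend=1)
        assert (a, b) == ("AA", "--")
        assert score == -12

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValidationError):
            pairwise_global_align("", "")

    def test_alignment_degaps_to_inputs(self):
        _, (a, b) = pairwise_global_align("MKVLACDE", "MKACDE")
        assert a.replace("-", "") == "MKVLACDE"
        assert b.replace("-", "") == "MKACDE"

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.text(alphabet=AA_ALPHABET, min_size=1, max_size=10),
           st.text(alphabet=AA_ALPHABET, min_size=1, max_size=10))
    def test_score_is_symmetric(self, a, b):
        assert pairwise_global_align(a, b)[0] == pairwise_global_align(b, a)[0]

    def test_matches_brute_force_on_short_pairs(self):
        m = blosum80()
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = "".join(rng.choice(list("ACDW"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACDW"), size=rng.integers(1, 7)))
            score, _ = pairwise_global_align(a, b, m, 10, 1)
            assert score == brute_force_score(a, b, m, 10, 1)

    def test_matches_biopython_aligner_convention(self):
        # independent implementation cross-check: PairwiseAligner with
        # open = -(go+ge), extend = -ge reproduces the open+ℓ·extend cost
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM80")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AA_ALPHABET), size=rng.integers(3, 15)))
            b = "".join(rng.choice(list(AA_ALPHABET), size=rng.integers(3, 15)))
            ours, _ = pairwise_global_align(a, b, gap_open=10, gap_extend=1)
            assert ours == aligner.score(a, b)


class TestKmerDistance:
    def test_identical_sequences_distance_zero(self):
        assert kmer_distance("MKVLACDE", "MKVLACDE") == 0.0

    def test_disjoint_kmer_sets_distance_one(self):
        assert kmer_distance("AAAA", "CCCC") == 1.0

    def test_multiset_semantics_match_enumeration(self):
        # shared 3-mer multiset of AAAA={AAA:2} and AAAC={AAA:1,AAC:1}
        # is {AAA:1}; denominator min(2,2)=2 -> distance 0.5
        assert kmer_distance("AAAA", "AAAC") == 0.5

    def test_short_sequence_falls_back_to_k1(self):
        assert kmer_distance("AC", "CA") == 0.0  # same 1-mer multiset


class TestGuideTree:
    def test_two_instances_single_cherry(self):
        t = build_guide_tree(["a", "b"], {"a": "ACDACD", "b": "ACDACD"})
        assert sorted(t.leaves) == ["a", "b"]
        assert t.left.is_leaf and t.right.is_leaf

    def test_forced_topology_and_tie_break(self):
        dmat = {frozenset(("A", "B")): 0.1, frozenset(("A", "C")): 0.9,
                frozenset(("B", "C")): 0.9}
        seq_to_id = {"sA": "A", "sB": "B", "sC": "C"}
        t = build_guide_tree(
            ["A", "B", "C"], {"A": "sA", "B": "sB", "C": "sC"},
            distance=lambda x, y: dmat[frozenset((seq_to_id[x], seq_to_id[y]))])
        inner = t.left if not t.left.is_leaf else t.right
        assert sorted(inner.leaves) == ["A", "B"]
        # equidistant triple: lexicographically smallest pair merges first
        t2 = build_guide_tree(["z", "y", "x"],
                              {"z": "1", "y": "2", "x": "3"},
                              distance=lambda a, b: 0.5)
        inner2 = t2.left if not t2.left.is_leaf else t2.right
        assert sorted(inner2.leaves) == ["x", "y"]

    def test_heights_non_decreasing_toward_root(self):
        rng = np.random.default_rng(1)
        seqs = {f"s{i}": "".join(rng.choice(list(AA_ALPHABET), size=30))
                for i in range(8)}

        def check(node: GuideTree):
            for child in (node.left, node.right):
                if child is not None and not child.is_leaf:
                    assert child.height <= node.height + 1e-12
                    check(child)

        check(build_guide_tree(list(seqs), seqs))

    def test_average_linkage_matches_scipy_on_tie_free_matrix(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(5)
        n = 6
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        D = D + D.T
        ids = [f"i{k}" for k in range(n)]
        lookup = {frozenset((ids[a], ids[b])): D[a, b]
                  for a in range(n) for b in range(a + 1, n)}
        t = build_guide_tree(ids, {i: i for i in ids},
                             distance=lambda x, y: lookup[frozenset((x, y))])
        Z = average(squareform(D))
        # root height of UPGMA = half the final merge distance
        assert t.height == pytest.approx(Z[-1, 2] / 2)


class TestProfilesAndProgressive:
    def test_single_sequence_profiles_reduce_to_pairwise(self):
        a, b = "MKVLACDE", "MKACDE"
        _, (pa, pb) = pairwise_global_align(a, b)
        merged = align_profiles(Profile([("a", a)]), Profile([("b", b)]))
        assert merged.rows == [("a", pa), ("b", pb)]

    def test_merge_preserves_row_count_and_width(self):
        pa = Profile([("a", "ACD"), ("b", "ACD")])
        pb = Profile([("c", "ACD")])
        out = align_profiles(pa, pb)
        assert len(out.rows) == 3
        assert out.length == 3
        assert all(s == "ACD" for _, s in out.rows)

    def test_identical_instances_align_gap_free(self):
        fam = make_family(["MKVLACDEHW"] * 5)
        aln = progressive_align(fam)
        assert aln.length == 10
        assert all("-" not in s for _, s in aln.rows)

    def test_single_leading_deletion_gives_one_gap_column(self):
        seq = "MKVLACDEHW"
        fam = make_family([seq, seq[1:]])
        aln = progressive_align(fam)
        # oracle: the pairwise alignment of the two sequences
        _, (pa, pb) = pairwise_global_align(seq, seq[1:])
        assert [s for _, s in aln.rows] == [pa, pb]
        assert sum(ch == "-" for _, s in aln.rows for ch in s) == 1

    def test_degapping_reproduces_instance_sequences(self):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list(AA_ALPHABET), size=30))
        seqs = []
        for _ in range(6):
            s = [c for c in base if rng.random() > 0.03]
            for i in range(len(s)):
                if rng.random() < 0.15:
                    s[i] = str(rng.choice(list(AA_ALPHABET)))
            seqs.append("".join(s))
        fam = make_family(seqs)
        aln = progressive_align(fam)
        for inst in fam.instances:
            assert aln.ungapped(inst.instance_id) == inst.sequence

    def test_col_map_strictly_increasing(self):
        fam = make_family(["MKVLACDEHW", "MKVACDEHW", "KVLACDEW"])
        aln = progressive_align(fam)
        for inst in fam.instances:
            cols = [aln.column_of(inst.instance_id, off)
                    for off in range(1, inst.length + 1)]
            assert all(c2 > c1 for c1, c2 in zip(cols, cols[1:]))

    def test_determinism_byte_identical(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list(AA_ALPHABET), size=25))
                for _ in range(5)]
        a1 = progressive_align(make_family(seqs))
        a2 = progressive_align(make_family(seqs))
        assert a1.rows == a2.rows

    def test_kelch_repeats_share_hotspot_column(self, kelch_like):
        _, _, fams = kelch_like
        aln = progressive_align(fams["PF01344"])
        c1 = aln.column_of("KEAP1_P:412-457", 12)
        c2 = aln.column_of("KEAP1_P:459-504", 12)
        assert c1 == c2 == 12


class TestExternalAlignment:
    def test_round_trip_preserves_col_map(self, tmp_path, kelch_like):
        _, _, fams = kelch_like
        fam = fams["PF01344"]
        aln = progressive_align(fam)
        path = tmp_path / "aln.fasta"
        write_aligned_fasta(aln, path)
        back = load_external_alignment(path, fam)
        assert back.rows == aln.rows
        for inst in fam.instances:
            for off in (1, 12, inst.length):
                assert back.column_of(inst.instance_id, off) == \
                       aln.column_of(inst.instance_id, off)

    def test_sequence_mismatch_names_row(self, tmp_path, kelch_like):
        _, _, fams = kelch_like
        fam = fams["PF01344"]
        aln = progressive_align(fam)
        rid, seq = aln.rows[0]
        bad = [(rid, ("A" if seq[0] != "A" else "C") + seq[1:]), aln.rows[1]]
        path = tmp_path / "bad.fasta"
        from domainhotspots.alignment import DomainAlignment
        write_aligned_fasta(DomainAlignment("PF01344", bad), path)
        with pytest.raises(ValidationError, match=rid):
            load_external_alignment(path, fam)

    def test_missing_instance_listed(self, tmp_path, kelch_like):
        _, _, fams = kelch_like
        fam = fams["PF01344"]
        aln = progressive_align(fam)
        from domainhotspots.alignment import DomainAlignment
        partial = DomainAlignment("PF01344", aln.rows[:1])
        path = tmp_path / "partial.fasta"
        write_aligned_fasta(partial, path)
        with pytest.raises(ValidationError, match="missing"):
            load_external_alignment(path, fam)
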