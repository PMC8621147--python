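"""Global alignment, identity matrices, and neighbor-joining trees."""

import io

import numpy as np
import pytest

from gliakit import (AlignParams, GeneSpec, build_gamma_gene, global_align,
                     identity_matrix, nj_tree, percent_identity,
                     tree_from_identity)
from gliakit.synthetic import diverge

LINEAR = AlignParams(nt_gap_open=-2, nt_gap_extend=-2)


class TestGlobalAlign:
    def test_identical_sequences_gapless(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.aligned_a == aln.aligned_b == "ACGTACGT"
        assert aln.score == 8.0

    def test_single_gap_linear_scoring(self):
        # match 1, mismatch −1, gap −2 linear: ACGT/AC-T scores 3·1 − 2 = 1
        aln = global_align("ACGT", "ACT", LINEAR)
        assert aln.score == 1.0
        assert (aln.aligned_a, aln.aligned_b) == ("ACGT", "AC-T")

    def test_symmetry_of_score(self):
        # optimal score is symmetric; the alignment strings themselves may
        # differ between equal-score optima because the tie-break prefers a
        # gap in the second sequence
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 60))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 60))))
            f = global_align(a, b)
            r = global_align(b, a)
            assert f.score == r.score
            assert r.aligned_b.replace("-", "") == a
            assert r.aligned_a.replace("-", "") == b

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            global_align("ACGTACGT", "MKLWQPED")

    def test_gap_removal_recovers_inputs(self):
        a, b = "ACGTTTACGGA", "ACGACGGATTT"
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_matches_affine_dp_oracle(self):
        # independent oracle: Biopython's global affine-gap aligner
        from Bio import Align
        oracle = Align.PairwiseAligner(match_score=1, mismatch_score=-1,
                                       open_gap_score=-5, extend_gap_score=-1,
                                       mode="global")
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 90))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 90))))
            assert global_align(a, b).score == pytest.approx(oracle.score(a, b))


class TestPercentIdentity:
    def test_identical_is_100(self):
        assert percent_identity(global_align("ACGT", "ACGT")) == 100.0

    def test_three_quarters(self):
        assert percent_identity(global_align("AAAA", "AAAT")) == 75.0

    def test_columns_le_ungapped_when_gapped(self):
        aln = global_align("ACGTACGTAC", "ACGTAC")
        assert "-" in aln.aligned_b
        assert percent_identity(aln, "columns") <= \
            percent_identity(aln, "ungapped")

    def test_near_identical_paralogs(self):
        # six substitutions in an 858-bp pair: 852/858 = 99.3%
        g = build_gamma_gene(GeneSpec(seed=3))
        p = diverge(g, 3, 3, seed=9)
        assert len(g.dna) == len(p.dna)
        nt = percent_identity(global_align(g.dna, p.dna))
        assert round(nt, 1) == round(100 * (len(g.dna) - 6) / len(g.dna), 1)


class TestIdentityMatrix:
    def test_single_sequence(self):
        im = identity_matrix({"a": "ACGT"}, {"a": "MK"})
        assert im.dual_triangle().iloc[0, 0] == 100.0

    def test_dual_triangle_layout(self):
        nt = {"x": "ACGTACGTACGT", "y": "ACGTACGTACGT"}
        aa = {"x": "MKLV", "y": "MKAA"}
        dt = identity_matrix(nt, aa).dual_triangle()
        assert dt.loc["x", "y"] == 100.0      # upper: NT
        assert dt.loc["y", "x"] == 50.0       # lower: AA
        assert dt.loc["x", "x"] == dt.loc["y", "y"] == 100.0

    def test_cells_match_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        nt = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60))
              for i in range(4)}
        aa = {f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
              for i in range(4)}
        im = identity_matrix(nt, aa)
        for i, li in enumerate(im.labels):
            for j, lj in enumerate(im.labels):
                if i < j:
                    expect = round(percent_identity(
                        global_align(nt[li], nt[lj])), 1)
                    assert im.nt.iloc[i, j] == expect

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        nt = {f"s{i}": "".join(rng.choice(list("ACGT"), size=50))
              for i in range(3)}
        aa = {f"s{i}": "".join(rng.choice(list("MKLVQP"), size=20))
              for i in range(3)}
        im1 = identity_matrix(nt, aa)
        order = ["s2", "s0", "s1"]
        im2 = identity_matrix({k: nt[k] for k in order},
                              {k: aa[k] for k in order})
        for x in im1.labels:
            for y in im1.labels:
                assert im1.nt.loc[x, y] == im2.nt.loc[x, y]

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label sets"):
            identity_matrix({"a": "ACGT"}, {"b": "MK"})


def _random_additive(rng, n):
    """Random binary tree with its exact leaf distance matrix and Newick."""
    labels = [f"t{i}" for i in range(n)]
    dist = {}
    clusters = [({lab: 0.0}, lab) for lab in labels]
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (da, na), (db, nb) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.5, 3.0, size=2).round(3)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[tuple(sorted((x, y)))] = dx + la + dy + lb
        merged = {x: d + la for x, d in da.items()} | \
                 {y: d + lb for y, d in db.items()}
        newick = f"({na}:{la},{nb}:{lb})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, newick))
    (da, na), (db, nb) = clusters
    lb = round(float(rng.uniform(0.5, 3.0)), 3)
    for x, dx in da.items():
        for y, dy in db.items():
            dist[tuple(sorted((x, y)))] = dx + dy + lb
    newick = f"({na},{nb}:{lb});"
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = dist[tuple(sorted((labels[a], labels[b])))]
    return labels, D, newick


class TestNeighborJoining:
    def test_two_taxa_split_edge(self):
        t = nj_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["A", "B"])
        assert t.to_newick() == "(A:1.5000,B:1.5000);"

    def test_three_point_formulas(self):
        D = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        t = nj_tree(D, ["A", "B", "C"])
        assert t.to_newick() == "(A:1.0000,B:1.0000,C:2.0000);"

    def test_additive_five_taxa_recovery(self):
        rng = np.random.default_rng(7)
        labels, D, true_nwk = _random_additive(rng, 5)
        t = nj_tree(D, labels)
        got = t.pairwise_distances()
        for a in range(5):
            for b in range(a + 1, 5):
                key = tuple(sorted((labels[a], labels[b])))
                assert got[key] == pytest.approx(D[a, b], abs=1e-9)

    def test_topology_matches_independent_nj(self):
        # cross-check against scikit-bio's NJ on the same matrix
        import skbio
        rng = np.random.default_rng(8)
        labels, D, true_nwk = _random_additive(rng, 6)
        mine = skbio.TreeNode.read(io.StringIO(nj_tree(D, labels).to_newick()))
        truth = skbio.TreeNode.read(io.StringIO(true_nwk))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, labels))
        assert mine.compare_rfd(truth) == 0
        assert mine.compare_rfd(ref) == 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((1, 1)), ["A"])
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(np.array([[0, np.nan], [np.nan, 0]]), ["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])

    def test_tree_from_identity_uses_aa_distance(self):
        rng = np.random.default_rng(9)
        nt = {f"s{i}": "".join(rng.choice(list("ACGT"), size=45))
              for i in range(3)}
        aa = {f"s{i}": "".join(rng.choice(list("MKLVQPE"), size=18))
              for i in range(3)}
        im = identity_matrix(nt, aa)
        t = tree_from_identity(im)
        assert sorted(t.leaf_names()) == sorted(im.labels)
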