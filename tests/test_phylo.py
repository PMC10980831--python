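"""Distance-based tree building: JC distances, NJ, UPGMA, bootstraps."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from regionbench.errors import DataError, InvalidArgument
from regionbench.msa import Alignment
from regionbench.phylo import (bootstrap_support, bootstrap_ani_dendrogram,
                               jc_distance_matrix, neighbor_joining,
                               scmg_tree, upgma)
from regionbench.simulate import evolve_alignment, simulate_tree
from regionbench.tree import parse_newick
from regionbench.treedist import rf_distance, splits


class TestJCDistances:
    def test_identical_rows(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert jc_distance_matrix(aln)["a", "b"] == 0.0

    def test_closed_form_at_p_03(self):
        # 3 of 10 columns differ -> d = -(3/4) ln(1 - 0.4)
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "CCCAAAAAAA"])
        assert jc_distance_matrix(aln)["a", "b"] == pytest.approx(
            -0.75 * np.log(0.6), abs=1e-12)

    def test_saturated_pair_capped(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "CCCCCCCCAA"])
        assert jc_distance_matrix(aln)["a", "b"] == 5.0

    def test_gaps_excluded_pairwise(self):
        aln = Alignment(["a", "b"], ["ACGT--", "ACGANN"])
        # comparable columns: first four; one differs
        assert jc_distance_matrix(aln)["a", "b"] == pytest.approx(
            -0.75 * np.log(1 - 4 * 0.25 / 3))

    def test_no_comparable_columns_is_an_error(self):
        aln = Alignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(DataError, match="a.*b|b.*a"):
            jc_distance_matrix(aln)


def _random_additive(n, seed):
    """A random binary tree and its exact patristic distance matrix."""
    t = simulate_tree(n, 1.0, 0.2, seed)
    labels, mat = t.pairwise_distances()
    return t, DistanceMatrix(mat, labels)


class TestNeighborJoining:
    def test_needs_three_taxa(self):
        with pytest.raises(InvalidArgument):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_three_point_formulas(self):
        D = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                           ["A", "B", "C"])
        t = neighbor_joining(D)
        lengths = {n.name: n.length for n in t.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_branch_lengths(self):
        truth = parse_newick("((A:1,B:2):1,(C:3,D:4));")
        labels, mat = truth.pairwise_distances()
        t = neighbor_joining(DistanceMatrix(mat, labels))
        assert rf_distance(t, truth) == 0
        _, rmat = t.pairwise_distances()
        assert np.allclose(rmat, mat, atol=1e-9)

    def test_consistency_on_additive_matrices(self):
        for seed in range(25):
            truth, D = _random_additive(8, seed)
            t = neighbor_joining(D)
            assert rf_distance(t, truth) == 0
            _, got = t.pairwise_distances()
            _, want = truth.pairwise_distances()
            assert np.allclose(got, want, atol=1e-9)

    def test_agrees_with_skbio_topology(self):
        from skbio.tree import nj as skbio_nj

        truth, D = _random_additive(10, seed=123)
        ours = neighbor_joining(D)
        sk_tree = parse_newick(str(skbio_nj(D)))
        assert rf_distance(ours, sk_tree) == 0


class TestUPGMA:
    def test_two_leaves_root_height(self):
        t = upgma(DistanceMatrix([[0, 0.1], [0.1, 0]], ["a", "b"]))
        depths = t.leaf_depths()
        assert depths["a"] == pytest.approx(0.05)
        assert depths["b"] == pytest.approx(0.05)

    def test_ultrametric_reconstruction(self):
        for seed in range(10):
            truth = simulate_tree(7, 1.0, 0.3, seed)  # ultrametric
            labels, mat = truth.pairwise_distances()
            t = upgma(DistanceMatrix(mat, labels))
            _, got = t.pairwise_distances()
            assert np.allclose(got, mat, atol=1e-9)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(3)
        mat = rng.random((6, 6))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0)
        t = upgma(DistanceMatrix(mat, list("abcdef")))
        depths = list(t.leaf_depths().values())
        assert max(depths) - min(depths) < 1e-9

    def test_tie_break_merges_smallest_label_pair(self):
        mat = np.array([[0, 1.0, 1.0, 2.0],
                        [1.0, 0, 2.0, 2.0],
                        [1.0, 2.0, 0, 2.0],
                        [2.0, 2.0, 2.0, 0]], dtype=float)
        t = upgma(DistanceMatrix(mat, ["a", "b", "c", "d"]))
        # ties (a,b) and (a,c) at 1.0: (a,b) merges first
        clusters = {frozenset(c.name for c in node.postorder()
                              if c.is_leaf)
                    for node in t.root.postorder() if not node.is_leaf}
        assert frozenset({"a", "b"}) in clusters


class TestBootstrap:
    def _two_clade_alignment(self, seed=0):
        truth = parse_newick(
            "((A:0.02,B:0.02):0.25,(C:0.02,D:0.02):0.25,E:0.27);")
        return truth, evolve_alignment(truth, 600, np.ones(600), seed=seed)

    def test_seed_determinism(self):
        _, aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, "nj", n_reps=30, seed=9)
        t2 = bootstrap_support(aln, "nj", n_reps=30, seed=9)
        assert t1.newick() == t2.newick()

    def test_deep_split_gets_high_support(self):
        truth, aln = self._two_clade_alignment(seed=4)
        t = bootstrap_support(aln, "nj", n_reps=100, seed=1)
        supports = [n.support for n in t.root.postorder()
                    if n.support is not None]
        assert supports and max(supports) >= 95

    def test_invalid_rep_count(self):
        _, aln = self._two_clade_alignment()
        with pytest.raises(InvalidArgument):
            bootstrap_support(aln, "nj", n_reps=0, seed=0)

    def test_identical_sequences_do_not_crash(self):
        aln = Alignment(list("abcd"), ["ACGTACGT"] * 4)
        t = bootstrap_support(aln, "upgma", n_reps=10, seed=0)
        assert sorted(t.leaf_names()) == list("abcd")

    def test_ani_bootstrap_determinism(self):
        frags = {("a", "b"): [99.0, 98.5], ("a", "c"): [90.0, 91.0],
                 ("b", "c"): [90.5, 89.5]}
        t1 = bootstrap_ani_dendrogram(frags, ["a", "b", "c"], 20, seed=2)
        t2 = bootstrap_ani_dendrogram(frags, ["a", "b", "c"], 20, seed=2)
        assert t1.newick() == t2.newick()


class TestSCMGTree:
    def test_recovers_true_tree_from_markers(self):
        from regionbench.simulate import SimConfig, simulate_genus

        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_species=8, strains_per_species=1,
                            genome_length=2040, seed=seed + 40)
            genus = simulate_genus(cfg)
            t = scmg_tree(genus.marker_alignments, n_reps=10, seed=0)
            hits += rf_distance(t, genus.true_tree) == 0
        assert hits >= 9

    def test_single_marker_equals_direct_build(self):
        truth = simulate_tree(6, 1.0, 0.1, seed=5)
        aln = evolve_alignment(truth, 500, np.ones(500), seed=6)
        direct = bootstrap_support(aln, "nj", n_reps=5, seed=1)
        via = scmg_tree([aln], n_reps=5, seed=1)
        assert via.newick() == direct.newick()

    def test_missing_genome_is_gap_filled(self):
        truth = simulate_tree(6, 1.0, 0.1, seed=8)
        alns = [evolve_alignment(truth, 300, np.ones(300), seed=m)
                for m in range(3)]
        reduced = Alignment(alns[1].labels[:-1], alns[1].rows[:-1])
        t = scmg_tree([alns[0], reduced, alns[2]], n_reps=5, seed=0)
        assert sorted(t.leaf_names()) == sorted(alns[0].labels)

    def test_disjoint_marker_sets_rejected(self):
        a = Alignment(["x", "y"], ["ACGT", "ACGA"])
        b = Alignment(["p", "q"], ["ACGT", "ACGA"])
        with pytest.raises(DataError):
            scmg_tree([a, b])


class TestTreeSerialization:
    def test_split_set_survives_newick_round_trip(self):
        for seed in range(5):
            t = simulate_tree(9, 1.0, 0.15, seed)
            back = parse_newick(t.newick())
            assert splits(t).masks == splits(back).masks
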