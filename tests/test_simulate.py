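"""Synthetic-genus generator: trees, sequence evolution, determinism."""

import numpy as np
import pytest

from regionbench.errors import InvalidArgument
from regionbench.simulate import (DEFAULT_REGION_MAP, SimConfig,
                                  default_region_rates, evolve_alignment,
                                  simulate_genus, simulate_tree,
                                  ssu_site_rates, write_genus)
from regionbench.tree import parse_newick


class TestSimulateTree:
    def test_two_taxa_branch_sum(self):
        t = simulate_tree(2, 1.0, 0.1, seed=1)
        assert sum(n.length for n in t.leaves()) == pytest.approx(0.2)

    def test_seed_determinism(self):
        a = simulate_tree(8, 1.0, 0.05, seed=7)
        b = simulate_tree(8, 1.0, 0.05, seed=7)
        assert a.newick() == b.newick()

    def test_different_seeds_differ(self):
        a = simulate_tree(8, 1.0, 0.05, seed=7)
        b = simulate_tree(8, 1.0, 0.05, seed=8)
        assert a.newick() != b.newick()

    def test_ultrametric_with_target_depth(self):
        t = simulate_tree(12, 1.0, 0.07, seed=3)
        depths = list(t.leaf_depths().values())
        assert max(depths) - min(depths) < 1e-12
        assert depths[0] == pytest.approx(0.07)

    def test_leaf_labels(self):
        t = simulate_tree(5, 1.0, 0.1, seed=0)
        assert sorted(t.leaf_names()) == [f"T{i}" for i in (1, 2, 3, 4, 5)]

    def test_too_few_taxa(self):
        with pytest.raises(InvalidArgument):
            simulate_tree(1, 1.0, 0.1, seed=0)


class TestEvolveAlignment:
    def test_zero_rates_freeze_the_root(self):
        t = simulate_tree(5, 1.0, 0.3, seed=2)
        aln = evolve_alignment(t, 200, np.zeros(200), seed=3)
        assert len(set(aln.rows)) == 1

    def test_jc_saturation_closed_form(self):
        # two leaves at total path 0.3: expected difference fraction
        # (3/4)(1 - exp(-4*0.3/3)) ~ 0.2473
        t = parse_newick("(A:0.15,B:0.15);")
        aln = evolve_alignment(t, 100_000, np.ones(100_000), seed=5)
        a, b = aln.rows
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        assert p == pytest.approx(0.75 * (1 - np.exp(-0.4)), abs=0.01)

    def test_k80_transition_bias(self):
        t = parse_newick("(A:0.25,B:0.25);")
        aln = evolve_alignment(t, 60_000, np.ones(60_000), model="K80",
                               seed=6, kappa=8.0)
        ts = tv = 0
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for x, y in zip(*aln.rows):
            if x != y:
                if (x, y) in transitions:
                    ts += 1
                else:
                    tv += 1
        assert ts > tv  # strong kappa: transitions dominate

    def test_seed_determinism(self):
        t = simulate_tree(6, 1.0, 0.1, seed=1)
        a = evolve_alignment(t, 500, np.ones(500), seed=9)
        b = evolve_alignment(t, 500, np.ones(500), seed=9)
        assert a.rows == b.rows

    def test_negative_rate_rejected(self):
        t = simulate_tree(3, 1.0, 0.1, seed=1)
        with pytest.raises(InvalidArgument):
            evolve_alignment(t, 3, [-1.0, 0.0, 1.0])


class TestSimConfig:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(InvalidArgument):
            SimConfig(region_map=(("a", 0, 100), ("b", 50, 150)))

    def test_empty_region_rejected(self):
        with pytest.raises(InvalidArgument):
            SimConfig(region_map=(("a", 100, 100),))

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgument):
            SimConfig(region_rate={"V4": -1.0})

    def test_planted_best_region(self):
        cfg = SimConfig(region_rate=default_region_rates(hot="V1-V3"))
        assert cfg.planted_best_region == "V1-V3"
        assert SimConfig().planted_best_region is None  # tie

    def test_primer_sites_are_invariant(self):
        rates = ssu_site_rates(SimConfig())
        from regionbench.simulate import SSU_PRIMER_SITES
        for start, site in SSU_PRIMER_SITES:
            assert (rates[start:start + len(site)] == 0).all()


class TestSimulateGenus:
    def test_genome_count_and_partition(self, small_genus):
        cfg = small_genus.config
        assert len(small_genus.genomes) == (cfg.n_species
                                            * cfg.strains_per_species)
        partition = small_genus.true_species_partition
        assert len(set(partition.values())) == cfg.n_species
        assert sorted(partition) == [g.genome_id
                                     for g in small_genus.genomes]

    def test_tree_leaves_match_genomes(self, small_genus):
        assert sorted(small_genus.true_tree.leaf_names()) == sorted(
            small_genus.true_species_partition)

    def test_byte_identical_reruns(self, tmp_path):
        cfg = SimConfig(n_species=4, strains_per_species=2,
                        genome_length=2040, n_marker_genes=2,
                        marker_length=200, seed=77)
        for sub in ("a", "b"):
            write_genus(simulate_genus(cfg), tmp_path / sub)
        for name in ("genomes.fasta", "ssu.fasta", "truth.nwk",
                     "truth.tsv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_region_rate_monotonicity(self):
        """Raising a window's multiplier never lowers its mean pairwise
        difference fraction (averaged over seeds)."""
        label, start, end = DEFAULT_REGION_MAP[2]
        means = []
        for rate in (0.0, 1.0, 5.0):
            diffs = []
            for seed in range(10):
                cfg = SimConfig(n_species=5, strains_per_species=1,
                                genome_length=2040, n_marker_genes=1,
                                marker_length=100,
                                region_rate={label: rate}, seed=seed)
                aln = simulate_genus(cfg).ssu_alignment
                arr = aln.to_array()[:, start:end]
                n = arr.shape[0]
                diffs.extend((arr[i] != arr[j]).mean()
                             for i in range(n) for j in range(i + 1, n))
            means.append(np.mean(diffs))
        assert means[0] <= means[1] <= means[2]
        assert means[0] == 0.0

    def test_ani_decays_with_patristic_distance(self, small_genus):
        from scipy.stats import spearmanr

        from regionbench.ani import ani_distance_matrix

        labels, tdist = small_genus.true_tree.pairwise_distances()
        dm, _ = ani_distance_matrix(small_genus.genome_records())
        tree_d, ani_d = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                tree_d.append(tdist[i, j])
                ani_d.append(100.0 * (1.0 - dm[labels[i], labels[j]]))
        rho, _ = spearmanr(tree_d, ani_d)
        # strong negative rank correlation; within-species pairs carry a
        # little estimator noise, so the magnitude is not exactly 1
        assert rho < -0.5

    def test_multi_copy_mode(self):
        cfg = SimConfig(n_species=3, strains_per_species=1,
                        genome_length=2040, n_marker_genes=1,
                        marker_length=100, n_16s_copies=3, seed=5)
        genus = simulate_genus(cfg)
        for g in genus.genomes:
            assert len(g.ssu) == 3
            assert {r.genome_id for r in g.ssu} == {g.genome_id}

    def test_indel_mode_changes_lengths(self):
        cfg = SimConfig(n_species=4, strains_per_species=1,
                        genome_length=2040, n_marker_genes=1,
                        marker_length=100, indel_rate=0.01, seed=6)
        genus = simulate_genus(cfg)
        lengths = {len(r.seq) for r in genus.ssu_records()}
        assert len(lengths) > 1
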