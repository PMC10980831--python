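"""Benchmark statistics: z-scores, best-region calls, Wilcoxon,
clustering scores, correlation, dereplicated subsampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regionbench.benchmark import (ani_adequacy, best_region, correlate,
                                   dereplicate_benchmark, genus_benchmark,
                                   heatmap_clusters,
                                   homogeneity_completeness,
                                   wilcoxon_signed_rank, zscore_rows)
from regionbench.errors import DataError, InvalidArgument


class TestZScoreRows:
    def test_documented_example(self):
        table = pd.DataFrame([[0.2, 0.4, 0.6]], columns=list("abc"))
        z = zscore_rows(table)
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_maps_to_zeros(self):
        table = pd.DataFrame([[0.3, 0.3, 0.3]], columns=list("abc"))
        assert (zscore_rows(table).to_numpy() == 0).all()

    def test_missing_cells_stay_missing(self):
        table = pd.DataFrame([[0.2, np.nan, 0.6]], columns=list("abc"))
        z = zscore_rows(table)
        assert np.isnan(z.iloc[0, 1])
        assert z.iloc[0, 0] == pytest.approx(-np.sqrt(0.5))

    def test_row_contract(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.random((20, 7)))
        z = zscore_rows(table)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestBestRegion:
    PANEL = ("V1-V3", "V3-V4", "V4")

    def test_unique_minimum(self):
        row = {"16S": 0.0, "V1-V3": 0.5, "V3-V4": 0.2, "V4": 0.8}
        assert best_region(row, self.PANEL) == "V3-V4"

    def test_full_length_excluded(self):
        row = {"16S": 0.0, "V1-V3": 0.5, "V3-V4": 0.6, "V4": 0.8}
        assert best_region(row, self.PANEL) == "V1-V3"

    def test_tie_breaks_in_panel_order(self):
        row = {"V1-V3": 0.4, "V3-V4": 0.4, "V4": 0.9}
        assert best_region(row, self.PANEL) == "V1-V3"

    def test_all_missing_is_an_error(self):
        with pytest.raises(DataError):
            best_region({"V1-V3": np.nan}, self.PANEL)


class TestWilcoxon:
    def test_identical_vectors(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_all_positive_differences_exact(self):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        w, p = wilcoxon_signed_rank(x, y)
        assert w == 0.0
        assert p == pytest.approx(2 / 32)

    def test_exact_matches_sign_enumeration(self):
        rng = np.random.default_rng(1)
        from scipy.stats import rankdata

        for _ in range(25):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w, p = wilcoxon_signed_rank(x, y)
            d = x - y
            d = d[d != 0]
            ranks = rankdata(np.abs(d))
            wp = ranks[d > 0].sum()
            dist = [sum(r for r, s in zip(ranks, signs) if s)
                    for signs in itertools.product([0, 1], repeat=len(d))]
            dist = np.array(dist)
            expected = min(1.0, 2 * min((dist <= wp).mean(),
                                        (dist >= wp).mean()))
            assert p == pytest.approx(expected, abs=1e-12)

    def test_large_n_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1, size=40)
        y = rng.normal(0.0, 1, size=40)
        _, p = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, correction=False,
                             mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgument):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestHomogeneityCompleteness:
    def test_identical_partitions(self):
        assert homogeneity_completeness([0, 0, 1, 1], [0, 0, 1, 1]) == (
            1.0, 1.0)

    def test_single_cluster_vs_two_classes(self):
        h, c = homogeneity_completeness([0, 0, 0, 0], [0, 0, 1, 1])
        assert (h, c) == (0.0, 1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import (completeness_score,
                                     homogeneity_score)

        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            pred = rng.integers(0, 4, n)
            true = rng.integers(0, 4, n)
            h, c = homogeneity_completeness(pred, true)
            assert h == pytest.approx(homogeneity_score(true, pred),
                                      abs=1e-12)
            assert c == pytest.approx(completeness_score(true, pred),
                                      abs=1e-12)

    def test_dict_inputs_aligned_on_keys(self):
        pred = {"b": 1, "a": 0, "c": 1}
        true = {"a": 0, "b": 1, "c": 1}
        assert homogeneity_completeness(pred, true) == (1.0, 1.0)


class TestHeatmapClusters:
    def test_identical_rows_cluster_together(self):
        z = pd.DataFrame([[1, 0], [1, 0], [0, 1]],
                         index=["g1", "g2", "g3"], dtype=float)
        clusters = heatmap_clusters(z, k=2)
        assert clusters["g1"] == clusters["g2"] != clusters["g3"]

    def test_two_separated_blocks(self):
        rng = np.random.default_rng(4)
        block1 = rng.normal(0, 0.01, (5, 4))
        block2 = rng.normal(10, 0.01, (5, 4))
        z = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"g{i}" for i in range(10)])
        clusters = heatmap_clusters(z, k=2)
        first = {clusters[f"g{i}"] for i in range(5)}
        second = {clusters[f"g{i}"] for i in range(5, 10)}
        assert len(first) == len(second) == 1 and first != second

    def test_k_larger_than_rows(self):
        z = pd.DataFrame([[1.0, 2.0]], index=["g"])
        with pytest.raises(InvalidArgument):
            heatmap_clusters(z, k=4)


class TestCorrelate:
    def test_perfectly_linear(self):
        r, p = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(InvalidArgument):
            correlate([1, 1, 1], [1, 2, 3])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r, _ = correlate(x, y)
        manual = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_spearman_option(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p = correlate(x, y, method="spearman")
        ref = spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)


class TestGenusBenchmark:
    def test_identical_alignments_give_identical_cells(self, small_genus):
        from regionbench.pipeline import analyze_synthetic_genus

        analysis = analyze_synthetic_genus(small_genus)
        full = analysis.alignments["16S"]
        row = genus_benchmark({"a": full, "b": full},
                              analysis.ani_dendrogram)
        assert row["a"] == row["b"]

    def test_small_alignment_cell_missing(self, small_genus):
        from regionbench.pipeline import analyze_synthetic_genus

        analysis = analyze_synthetic_genus(small_genus)
        tiny = analysis.alignments["16S"]
        tiny = tiny.select(tiny.labels[:3])
        row = genus_benchmark({"tiny": tiny}, analysis.ani_dendrogram)
        assert np.isnan(row["tiny"])


class TestAniAdequacy:
    def test_identical_trees_everywhere(self, small_genus):
        t = small_genus.true_tree
        trees = {f"genus{i}": {"ANI": t, "16S": t} for i in range(3)}
        scmg = {f"genus{i}": t for i in range(3)}
        table, tests, mean_ani = ani_adequacy(trees, scmg)
        assert (table.to_numpy() == 0).all()
        assert mean_ani == 0.0
        assert tests["16S"][1] == 1.0

    def test_single_genus_refused(self, small_genus):
        t = small_genus.true_tree
        with pytest.raises(DataError):
            ani_adequacy({"g": {"ANI": t, "16S": t}}, {"g": t})


class TestDereplicateBenchmark:
    def test_one_genome_per_group_has_zero_variance(self):
        from regionbench.ani import ani_distance_matrix, ani_groups
        from regionbench.pipeline import build_region_alignments
        from regionbench.simulate import SimConfig, simulate_genus

        genus = simulate_genus(SimConfig(n_species=5,
                                         strains_per_species=1,
                                         genome_length=4080,
                                         n_marker_genes=1,
                                         marker_length=100, seed=21))
        alns, _ = build_region_alignments(genus.ssu_records())
        dm, _ = ani_distance_matrix(genus.genome_records())
        groups = ani_groups(dm)
        assert groups.n_groups == len(genus.genomes)
        result = dereplicate_benchmark(alns["16S"], dm, groups,
                                       repeats=5, seed=1)
        assert result.replicate_jrf == [result.full_set_jrf] * 5

    def test_zero_repeats_rejected(self, small_genus):
        from regionbench.ani import ani_distance_matrix, ani_groups
        from regionbench.pipeline import build_region_alignments

        alns, _ = build_region_alignments(small_genus.ssu_records())
        dm, _ = ani_distance_matrix(small_genus.genome_records())
        with pytest.raises(InvalidArgument):
            dereplicate_benchmark(alns["16S"], dm, ani_groups(dm),
                                  repeats=0, seed=0)
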