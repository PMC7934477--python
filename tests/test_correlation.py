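"""Gene-gene correlation structure, declining cluster, enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from txhet import (
    CohortConfig,
    cluster_enrichment,
    correlation_sd_compare,
    declining_cluster,
    gene_correlations,
    simulate_pair,
)
from txhet.synthetic import GeneSpec, SyntheticTruth

from conftest import make_matrix


def _pair(rng, n_genes=20, n_cells=30):
    a = make_matrix(rng.random((n_genes, n_cells)) * 20 + 5)
    b = make_matrix(rng.random((n_genes, n_cells)) * 20 + 5)
    return a, b


class TestGeneCorrelations:
    def test_brute_force_spearman_oracle(self, rng):
        arr = rng.random((4, 15)) * 10 + 6
        m = make_matrix(arr)
        summary = gene_correlations(m, m, all_genes=True)
        for i in range(4):
            for j in range(4):
                ri = stats.rankdata(arr[i])
                rj = stats.rankdata(arr[j])
                expected = np.corrcoef(ri, rj)[0, 1]
                assert summary.c_wt.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_gene_has_unit_correlation(self, rng):
        arr = rng.random((3, 20)) * 10 + 6
        arr[1] = arr[0]  # gene2 == gene1
        summary = gene_correlations(make_matrix(arr), make_matrix(arr), all_genes=True)
        assert summary.c_wt.iloc[0, 1] == pytest.approx(1.0)
        assert summary.avg_sq["wt"].iloc[0] >= 0.5

    def test_constant_gene_flagged_and_excluded(self, rng):
        arr = rng.random((4, 15)) + 5
        arr[2] = 7.0
        summary = gene_correlations(make_matrix(arr), make_matrix(arr), all_genes=True)
        assert summary.degenerate_genes == ["g2"]
        assert np.isnan(summary.c_wt.iloc[2, 0])
        assert np.isfinite(summary.avg_sq["wt"].drop("g2")).all()

    def test_sq_diff_zero_for_same_matrix(self, rng):
        a, _ = _pair(rng)
        summary = gene_correlations(a, a, all_genes=True)
        assert np.abs(summary.sq_diff.to_numpy()).max() == 0.0

    def test_avg_sq_bounds_and_mean_identity(self, rng):
        a, b = _pair(rng)
        s = gene_correlations(a, b, all_genes=True)
        assert ((s.avg_sq >= 0) & (s.avg_sq <= 1)).all().all()
        # mean over off-diagonal pairs of sq_diff == difference of mean squared correlations
        n = s.sq_diff.shape[0]
        off = ~np.eye(n, dtype=bool)
        lhs = s.sq_diff.to_numpy()[off].mean()
        rhs = (s.c_wt.to_numpy()[off] ** 2).mean() - (s.c_mut.to_numpy()[off] ** 2).mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_too_few_cells_rejected(self, rng):
        a = make_matrix(rng.random((5, 8)) + 5)
        with pytest.raises(ValueError, match="10 cells"):
            gene_correlations(a, a, all_genes=True)


class TestCorrelationSdCompare:
    def test_planted_module_widens_correlation_dispersion(self):
        # 15 correlated module genes among 40: WT mixes high and null pairs,
        # so its correlation distribution is wider than the decorrelated mutant's
        specs = [GeneSpec(f"g{i}", "gaussian", (1, 0, 0), mu=30, sigma=4) for i in range(40)]
        truth = SyntheticTruth(module_gene_ids={f"g{i}" for i in range(15)})
        cfg = CohortConfig(n_genes=40, n_cells_per_condition=150, module_size=15,
                           module_corr_by_condition=(0.8, 0.0), seed=2)
        w, m, _ = simulate_pair(cfg, specs=specs, truth=truth)
        out, t, p = correlation_sd_compare(w, m, w.gene_ids, n_replicates=5, seed=0)
        assert out["wt"][0] > out["mut"][0]
        assert p < 0.05

    def test_null_sd_matches_theory(self):
        # independent genes: Spearman sd ~ 1/sqrt(n_cells - 1)
        rng = np.random.default_rng(4)
        n_cells = 200
        w = make_matrix(rng.random((60, n_cells)) * 10 + 5)
        m = make_matrix(rng.random((60, n_cells)) * 10 + 5)
        out, _, _ = correlation_sd_compare(w, m, w.gene_ids, n_replicates=3, subsample_frac=1.0, seed=0)
        expected = 1 / np.sqrt(n_cells - 1)
        assert abs(out["wt"][0] - expected) / expected < 0.2

    def test_subsample_too_small_raises(self, rng):
        a, b = _pair(rng, n_cells=11)
        with pytest.raises(ValueError, match="too small"):
            correlation_sd_compare(a, b, a.gene_ids, subsample_frac=0.5)


@pytest.fixture(scope="module")
def planted_summary():
    specs = [GeneSpec(f"M{i:03d}", "gaussian", (1, 0, 0), mu=25, sigma=3) for i in range(60)]
    specs += [GeneSpec(f"B{i:03d}", "gaussian", (1, 0, 0), mu=25, sigma=3) for i in range(140)]
    truth = SyntheticTruth(module_gene_ids={f"M{i:03d}" for i in range(60)})
    cfg = CohortConfig(n_genes=200, n_cells_per_condition=120, module_size=60,
                       module_corr_by_condition=(0.7, 0.0), seed=8)
    w, m, _ = simulate_pair(cfg, specs=specs, truth=truth)
    return gene_correlations(w, m, all_genes=True), truth


class TestDecliningCluster:
    def test_planted_block_recovered(self, planted_summary):
        summary, truth = planted_summary
        res = declining_cluster(summary, seed=0)
        jac = len(res.members & truth.module_gene_ids) / len(res.members | truth.module_gene_ids)
        assert jac >= 0.8
        assert not res.no_structure

    def test_deterministic_under_fixed_seed(self, planted_summary):
        summary, _ = planted_summary
        assert declining_cluster(summary, seed=3).members == declining_cluster(summary, seed=3).members

    def test_null_behavior_documented(self, rng):
        a = make_matrix(rng.random((50, 40)) * 10 + 5)
        b = make_matrix(rng.random((50, 40)) * 10 + 5)
        summary = gene_correlations(a, b, all_genes=True)
        res = declining_cluster(summary, seed=0)
        assert res.no_structure == (res.silhouette < 0.1)
        assert res.no_structure  # unstructured noise has no separated clusters
        # the alternative "largest cluster" rule returns the majority block
        largest = declining_cluster(summary, seed=0, select="largest")
        assert 0.4 <= len(largest.members) / 50 <= 1.0

    def test_k_too_large_raises(self, rng):
        a, b = _pair(rng, n_genes=5, n_cells=12)
        with pytest.raises(ValueError, match="k="):
            declining_cluster(gene_correlations(a, b, all_genes=True), k=10)


class TestClusterEnrichment:
    def test_cluster_equals_background_p_one(self):
        bg = {f"g{i}" for i in range(30)}
        df = cluster_enrichment(bg, {"s": {f"g{i}" for i in range(10)}}, bg)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_tail_sum(self):
        bg = {f"g{i}" for i in range(100)}
        ann = {f"g{i}" for i in range(10)}
        cluster = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        df = cluster_enrichment(cluster, {"a": ann}, bg)
        closed = sum(math.comb(10, x) * math.comb(90, 10 - x) for x in range(5, 11)) / math.comb(100, 10)
        assert df["p"].iloc[0] == pytest.approx(closed, rel=1e-12)

    def test_depleted_overlap_gives_large_p(self):
        bg = {f"g{i}" for i in range(100)}
        ann = {f"g{i}" for i in range(50)}      # expect 25 of 50 by chance
        cluster = {f"g{i}" for i in range(45, 95)}  # overlap 5, far below expectation
        df = cluster_enrichment(cluster, {"a": ann}, bg)
        assert df["p"].iloc[0] > 0.5

    def test_disjoint_annotation_warns_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        with pytest.warns(UserWarning, match="disjoint"):
            df = cluster_enrichment({"g1"}, {"a": {"x1", "x2"}}, bg)
        assert df["p"].iloc[0] == 1.0

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            cluster_enrichment({"zz"}, {"a": {"g1"}}, {"g1", "g2"})
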