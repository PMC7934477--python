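"""Differential-variability statistics: mean filters, trimmed CV, DVSM calls,
rank scores, DV calls, differential expression, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from txhet import (
    differential_expression,
    dv_call,
    dv_enrichment,
    dvsm_cv_call,
    dvsm_model_call,
    mean_difference_index,
    similar_mean_filter,
    trimmed_cv,
    variability_rank_score,
    variability_table,
)
from txhet.mixture import MixtureFit, classify_shape, fit_mixture
from txhet.variability import (
    MORE_VARIABLE_MUT_TYPE_I,
    MORE_VARIABLE_MUT_TYPE_II,
    NOT_APPLICABLE,
    NOT_DV,
)

from conftest import make_matrix


def gaussian_fit(pi_g, mu=10.0, sigma=1.0, converged=True):
    fit = MixtureFit(pi=np.array([pi_g, (1 - pi_g) / 2, (1 - pi_g) / 2]), mu=mu, sigma=sigma,
                     rate=1.0, loglik=0.0, n_iter=5, converged=converged)
    fit.shape_class = classify_shape(fit)
    return fit


class TestMeanDifferenceIndex:
    def test_direct_values(self):
        assert mean_difference_index(1, 1) == 0
        assert mean_difference_index(1, 2) == pytest.approx(1 / 3)
        assert mean_difference_index(0.96, 1.04) == pytest.approx(0.04)
        assert np.isnan(mean_difference_index(0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
    def test_antisymmetry(self, a, b):
        assert mean_difference_index(a, b) == -mean_difference_index(b, a)


class TestSimilarMeanFilter:
    def _pair(self, mean_wt, mean_mut, detect_frac=1.0, n=40):
        aw = np.full((1, n), mean_wt)
        am = np.full((1, n), mean_mut)
        if detect_frac < 1:
            aw[0, : int(n * (1 - detect_frac))] = 0
        return make_matrix(aw), make_matrix(am)

    def test_boundary_index_excluded(self):
        w, m = self._pair(9.5, 10.5)  # index = 1/20 = 0.05 exactly -> strict cutoff excludes
        assert similar_mean_filter(w, m) == []

    def test_low_detection_excluded(self):
        w, m = self._pair(10, 10, detect_frac=0.4)
        assert similar_mean_filter(w, m) == []

    def test_low_mean_excluded(self):
        w, m = self._pair(4.9, 4.9)
        assert similar_mean_filter(w, m) == []

    def test_similar_gene_kept(self):
        w, m = self._pair(10.0, 10.2)
        assert similar_mean_filter(w, m) == ["g0"]


class TestTrimmedCV:
    def test_constant_vector_zero(self):
        assert trimmed_cv(np.full(30, 4.0)) == 0.0

    def test_outlier_removed(self):
        # one extreme cell inflates the raw CV ~25-fold; trimming kills it
        x = np.array([10.0] * 99 + [1000.0])
        assert trimmed_cv(x) == 0.0
        assert x.std(ddof=1) / x.mean() > 4

    def test_normal_sample_matches_truncation_oracle(self):
        # removing both 5% tails of N(mu, sigma) shrinks the sd by
        # sqrt(1 - 2 z phi(z) / 0.9) with z = Phi^-1(0.95) ~ 0.789
        from scipy.stats import norm
        z = norm.ppf(0.95)
        shrink = np.sqrt(1 - 2 * z * norm.pdf(z) / 0.9)
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, 1000)
        t = trimmed_cv(x)
        raw = x.std(ddof=1) / x.mean()
        assert t < raw
        assert abs(t - 0.2 * shrink) / (0.2 * shrink) < 0.1
        assert abs(raw - 0.2) / 0.2 < 0.1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="20"):
            trimmed_cv(np.arange(10))

    def test_zero_trimmed_mean_flagged(self):
        assert np.isnan(trimmed_cv(np.zeros(25)))


class TestDVSMModelCall:
    def test_identical_pure_gaussians_not_dv(self, rng):
        x = rng.normal(10, 1, 200)
        call, (lo, hi) = dvsm_model_call(x, x.copy(), gaussian_fit(1.0), gaussian_fit(1.0),
                                         n_boot=500, seed=0)
        assert call == NOT_DV and lo <= 1 <= hi

    def test_type_two_call_for_mixed_mutant(self, rng):
        x = rng.normal(10, 1, 100)
        call, _ = dvsm_model_call(x, x, gaussian_fit(0.95), gaussian_fit(0.5), n_boot=100, seed=0)
        assert call == MORE_VARIABLE_MUT_TYPE_II

    def test_borderline_gaussian_fraction_not_applicable(self, rng):
        # other condition at pi_G between 0.8 and 0.9: neither type I nor II
        x = rng.normal(10, 1, 100)
        call, _ = dvsm_model_call(x, x, gaussian_fit(0.95), gaussian_fit(0.85), n_boot=100, seed=0)
        assert call == NOT_APPLICABLE

    def test_unconverged_fit_not_applicable(self, rng):
        x = rng.normal(10, 1, 100)
        call, _ = dvsm_model_call(x, x, gaussian_fit(1.0, converged=False), gaussian_fit(1.0),
                                  n_boot=100, seed=0)
        assert call == NOT_APPLICABLE

    def test_power_for_doubled_sd(self):
        hits = 0
        trials = 25
        for s in range(trials):
            r = np.random.default_rng(500 + s)
            xw = np.clip(r.normal(20, 2, 100), 0, None)
            xm = np.clip(r.normal(20, 6, 100), 0, None)  # sd ratio 3
            fw, fm = fit_mixture(xw, seed=1, n_starts=2), fit_mixture(xm, seed=1, n_starts=2)
            call, _ = dvsm_model_call(xw, xm, fw, fm, n_boot=500, seed=s)
            hits += call == MORE_VARIABLE_MUT_TYPE_I
        assert hits >= 0.95 * trials


class TestDVSMCVCall:
    def test_null_ci_contains_one(self, rng):
        x = rng.normal(10, 2, 100)
        (lo, hi), call, p = dvsm_cv_call(x, x.copy(), n_boot=300, n_perm=300, seed=0)
        assert lo <= 1 <= hi and call == NOT_DV

    def test_planted_cv_ratio_detected(self):
        hits = 0
        trials = 20
        for s in range(trials):
            r = np.random.default_rng(700 + s)
            xw = np.clip(r.normal(20, 2, 80), 0, None)
            xm = np.clip(r.normal(20, 4, 80), 0, None)  # CV ratio 2
            _, _, p = dvsm_cv_call(xw, xm, n_boot=300, n_perm=500, seed=s)
            hits += p < 0.05
        assert hits >= 0.8 * trials

    def test_min_reportable_p_resolution(self, rng):
        xw = rng.normal(20, 1, 60)
        xm = rng.normal(20, 8, 60)
        _, _, p = dvsm_cv_call(xw, xm, n_boot=100, n_perm=200, seed=0)
        assert p >= 1 / 201  # resolution of a 200-permutation test

    def test_degenerate_input_not_applicable(self):
        (lo, hi), call, p = dvsm_cv_call(np.zeros(30), np.ones(30), n_boot=50, n_perm=50)
        assert call == NOT_APPLICABLE and np.isnan(p)


class TestVariabilityRankScore:
    def test_hand_oracle_window3(self):
        means = pd.Series([1, 2, 3, 4, 5], index=list("abcde"), dtype=float)
        cvs = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        s = variability_rank_score(means, cvs, window=3)
        # windows (a,b,c),(b,c,d),(c,d,e); c ranks 3rd, 2nd, 1st -> (1 + 0.5 + 0)/3
        assert s["c"] == pytest.approx(0.5)
        assert s[["a", "b", "d", "e"]].isna().all()

    def test_equal_cvs_score_half(self):
        s = variability_rank_score(pd.Series(np.arange(20.0)), pd.Series(np.ones(20)), window=5)
        assert (s.dropna() == 0.5).all()

    def test_monotone_cv_transform_invariance(self, rng):
        means = pd.Series(rng.uniform(1, 100, 50))
        cvs = pd.Series(rng.uniform(0.1, 1, 50))
        a = variability_rank_score(means, cvs, window=10)
        b = variability_rank_score(means, np.exp(3 * cvs), window=10)  # strictly monotone
        pd.testing.assert_series_equal(a, b)

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError, match="at least"):
            variability_rank_score(pd.Series([1.0, 2.0]), pd.Series([0.1, 0.2]), window=3)


class TestDVCall:
    def test_identical_scores_no_calls(self):
        s = pd.Series(np.linspace(0, 1, 20))
        res = dv_call(s, s.copy())
        assert (res["dv_call"] == "none").all()

    def test_one_std_superset_of_two_std(self, rng):
        wt = pd.Series(rng.uniform(0, 1, 200))
        mut = wt + rng.normal(0, 0.1, 200)
        dv2 = set(dv_call(wt, mut, n_std=2).query("dv_call != 'none'").index)
        dv1 = set(dv_call(wt, mut, n_std=1).query("dv_call != 'none'").index)
        assert dv2 <= dv1

    def test_direction_matches_sign(self, rng):
        wt = pd.Series(rng.uniform(0.4, 0.6, 100))
        mut = wt.copy()
        mut.iloc[0] += 0.35
        mut.iloc[1] -= 0.35
        res = dv_call(wt, mut, n_std=2)
        assert res["dv_call"].iloc[0] == "more_variable_mut"
        assert res["dv_call"].iloc[1] == "more_variable_wt"

    def test_too_few_genes_raises(self):
        s = pd.Series([0.1] * 5)
        with pytest.raises(ValueError, match="10"):
            dv_call(s, s)


class TestDifferentialExpression:
    def test_identical_conditions_no_de(self, rng):
        m = make_matrix(rng.random((30, 20)) * 50)
        de = differential_expression(m, m)
        assert de["de"].sum() == 0

    def test_expression_sum_rule_excludes_low_genes(self, rng):
        # 4-fold gene but a_wt + a_mut < 3: excluded
        n = 30
        aw = np.abs(np.full((1, n), 0.5) + rng.normal(0, 0.05, (1, n)))
        am = aw * 4
        de = differential_expression(make_matrix(aw), make_matrix(am))
        a_sum = de["a_wt"].iloc[0] + de["a_mut"].iloc[0]
        assert a_sum < 3 and not de["de"].iloc[0]

    def test_strong_fold_change_called(self, rng):
        n = 40
        aw = np.abs(rng.normal(10, 1, (1, n)))
        am = np.abs(rng.normal(40, 4, (1, n)))
        filler_w = rng.random((20, n)) * 10 + 5
        de = differential_expression(make_matrix(np.vstack([aw, filler_w])),
                                     make_matrix(np.vstack([am, filler_w])))
        assert bool(de["de"].iloc[0])


class TestDVEnrichment:
    def test_annotation_equals_background(self):
        bg = {f"g{i}" for i in range(50)}
        _, p = dv_enrichment({f"g{i}" for i in range(10)}, bg, bg)
        assert p == pytest.approx(1.0)

    def test_empty_set_warns_p_one(self):
        with pytest.warns(UserWarning, match="empty"):
            overlap, p = dv_enrichment(set(), {"g1"}, {"g1", "g2"})
        assert (overlap, p) == (0, 1.0)

    def test_closed_form_toy(self):
        import math
        bg = {f"g{i}" for i in range(100)}
        ann = {f"g{i}" for i in range(10)}
        dv = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(90, 95)}
        _, p = dv_enrichment(dv, ann, bg)
        closed = sum(math.comb(10, x) * math.comb(90, 10 - x) for x in range(5, 11)) / math.comb(100, 10)
        assert p == pytest.approx(closed, rel=1e-12)


def test_variability_table_end_to_end(rng):
    n_genes, n_cells = 80, 60
    arr_w = np.abs(rng.normal(20, 3, (n_genes, n_cells)))
    arr_m = arr_w + rng.normal(0, 0.5, (n_genes, n_cells))
    arr_m[0] = np.abs(rng.normal(20, 9, n_cells))  # one high-variance gene
    w, m = make_matrix(np.abs(arr_w)), make_matrix(np.abs(arr_m))
    tab = variability_table(w, m, mean_cutoff=0.05, n_boot=200, n_perm=200, window=20,
                            seed=0, run_model_calls=False)
    assert len(tab) == n_genes
    assert tab["similar_mean"].sum() > 0
    interior = tab["rank_score_wt"].dropna()
    assert ((interior >= 0) & (interior <= 1)).all()
    assert {"dv_call_2std", "dvsm_cv_call", "perm_p"} <= set(tab.columns)
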