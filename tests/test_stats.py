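"""Group statistics: t-tests, permutations, FDR, robustness, cohort tables."""

import numpy as np
import pytest
from scipy import stats as sps

from oscillome.stats import (
    RobustnessConfig,
    anova_from_summary,
    chi_square_counts,
    compare_groups,
    fdr_bh,
    feature_ttest,
    network_average_t,
    permutation_pvalues,
    subsample_robustness,
)


class TestFeatureTTest:
    def test_hand_computed_example(self):
        t, p = feature_ttest(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
        assert t[0] == pytest.approx(-3.674, abs=1e-3)
        assert p[0] == pytest.approx(0.0213, abs=5e-4)

    def test_matches_scipy_on_random_data(self, rng):
        a = rng.standard_normal((12, 30))
        b = rng.standard_normal((9, 30)) + 0.3
        t, p = feature_ttest(a, b)
        ref = sps.ttest_ind(a, b, axis=0)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_identical_groups_give_t0_p1(self):
        x = np.arange(12.0).reshape(4, 3)
        t, p = feature_ttest(x, x)
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)

    def test_swapping_groups_flips_t_keeps_p(self, rng):
        a = rng.standard_normal((8, 5))
        b = rng.standard_normal((10, 5)) + 0.5
        t1, p1 = feature_ttest(a, b)
        t2, p2 = feature_ttest(b, a)
        np.testing.assert_allclose(t1, -t2)
        np.testing.assert_allclose(p1, p2)

    def test_zero_pooled_variance_warns(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p = feature_ttest(np.ones((3, 1)), np.ones((3, 1)))
        assert t[0] == 0.0 and p[0] == 1.0


class TestPermutationPvalues:
    def test_lower_bound_is_one_over_nperm_plus_one(self, rng):
        X = np.vstack([rng.standard_normal((10, 3)), rng.standard_normal((10, 3)) + 50.0])
        y = np.repeat(["a", "b"], 10)
        p = permutation_pvalues(X, y, n_perm=99, seed=0)
        assert p.min() >= 1 / 100
        # huge effect saturates; only group-preserving permutations can tie
        assert (p <= 2 / 100).all()

    def test_null_rejection_rate_is_calibrated(self, rng):
        n_feat = 2000
        X = rng.standard_normal((40, n_feat))
        y = np.repeat([0, 1], 20)
        p = permutation_pvalues(X, y, n_perm=500, seed=1)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(rate - 0.05) < 1.96 * se + 0.01

    def test_agrees_with_parametric_p_for_gaussian_null(self, rng):
        X = rng.standard_normal((60, 50))
        y = np.repeat([0, 1], 30)
        p_perm = permutation_pvalues(X, y, n_perm=1000, seed=2)
        _, p_par = feature_ttest(X[:30], X[30:])
        assert np.abs(p_perm - p_par).max() < 0.05

    def test_invalid_nperm_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalues(rng.standard_normal((6, 2)), [0, 0, 0, 1, 1, 1], n_perm=0)


class TestFDR:
    def test_all_ones_rejects_nothing(self):
        reject, adj = fdr_bh(np.ones(10))
        assert not reject.any()
        np.testing.assert_array_equal(adj, 1.0)

    def test_step_up_on_the_six_value_example(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06])
        reject, adj = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(reject, [True, True, False, False, False, False])

    def test_single_test_equals_raw_threshold(self):
        reject, adj = fdr_bh(np.array([0.04]), q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_rejections_superset_of_bonferroni(self, rng):
        p = rng.uniform(0, 1, 200) ** 3
        reject, _ = fdr_bh(p, q=0.05)
        bonf = p < 0.05 / p.size
        assert (reject | ~bonf).all()

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))


class TestSubsampleRobustness:
    def test_strong_effect_is_selected_in_every_replicate(self, rng):
        X = rng.standard_normal((60, 20))
        X[30:, 0] += 2.0  # d = 2 planted in feature 0
        y = np.repeat([0, 1], 30)
        res = subsample_robustness(X, y, RobustnessConfig(), seed=0)
        assert res.selection_frequency[0] == 1.0
        assert res.robust[0]

    def test_null_features_rarely_selected(self, rng):
        X = rng.standard_normal((60, 30))
        y = np.repeat([0, 1], 30)
        res = subsample_robustness(X, y, RobustnessConfig(), seed=1)
        assert res.selection_frequency.max() <= 0.1

    def test_seeded_runs_are_identical(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.repeat([0, 1], 20)
        r1 = subsample_robustness(X, y, seed=5)
        r2 = subsample_robustness(X, y, seed=5)
        np.testing.assert_array_equal(r1.robust, r2.robust)
        np.testing.assert_array_equal(r1.selection_frequency, r2.selection_frequency)

    def test_full_fraction_reduces_to_the_plain_significant_mask(self, rng):
        X = rng.standard_normal((30, 15))
        X[15:, :3] += 1.5
        y = np.repeat([0, 1], 15)
        cfg = RobustnessConfig(n_replicates=5, subsample_fraction=1.0)
        res = subsample_robustness(X, y, cfg, seed=2)
        _, p = feature_ttest(X[:15], X[15:])
        reject, _ = fdr_bh(p, q=cfg.alpha)
        np.testing.assert_array_equal(res.robust, reject)

    def test_too_small_groups_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        y = [0, 0, 1, 1]
        with pytest.raises(ValueError, match="small"):
            subsample_robustness(X, y, RobustnessConfig(subsample_fraction=0.5))


class TestNetworkAverageT:
    def test_constant_matrix_averages_to_the_constant(self):
        t = np.full((4, 4), 2.5)
        out = network_average_t(t, ["A", "A", "B", "B"])
        assert (out.values == 2.5).all()

    def test_hand_computed_two_network_example(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 2.0
        t[0, 2] = t[2, 0] = 4.0
        t[1, 2] = t[2, 1] = 6.0
        out = network_average_t(t, ["A", "A", "B"])
        assert out.loc["A", "A"] == pytest.approx(2.0)
        assert out.loc["A", "B"] == pytest.approx(5.0)
        assert np.isnan(out.loc["B", "B"])  # single-region network: no pair

    def test_symmetric_input_gives_symmetric_output(self, rng):
        t = rng.standard_normal((6, 6))
        t = (t + t.T) / 2
        out = network_average_t(t, ["A", "B", "A", "C", "B", "C"])
        np.testing.assert_allclose(out.values, out.values.T, atol=1e-12)

    def test_invariant_to_consistent_region_permutation(self, rng):
        t = rng.standard_normal((6, 6))
        t = (t + t.T) / 2
        labels = np.array(["A", "B", "A", "C", "B", "C"])
        perm = rng.permutation(6)
        base = network_average_t(t, labels)
        permuted = network_average_t(t[np.ix_(perm, perm)], labels[perm])
        nets = list(base.index)
        np.testing.assert_allclose(
            base.values, permuted.loc[nets, nets].values, atol=1e-12
        )


class TestCohortTableStats:
    def test_handedness_chi_square_matches_the_published_table(self):
        chi2, df, p = chi_square_counts([[91, 7], [94, 2], [31, 0]])
        assert chi2 == pytest.approx(4.731, abs=1e-3)
        assert df == 2

    def test_matches_scipy_chi2_contingency(self, rng):
        table = rng.integers(5, 60, (3, 2))
        chi2, df, p = chi_square_counts(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_proportional_rows_give_zero(self):
        chi2, _, p = chi_square_counts([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_expected_zero_cell_errors(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_counts([[5, 0], [7, 0]])

    def test_age_anova_matches_the_published_table(self):
        F, df1, df2, p = anova_from_summary(
            [24.15, 24.15, 25.03], [7.17, 7.29, 7.90], [98, 96, 31]
        )
        assert F == pytest.approx(0.194, abs=5e-3)
        assert (df1, df2) == (2, 222)
        assert p == pytest.approx(0.824, abs=5e-3)

    def test_anova_from_summary_matches_scipy_on_raw_data(self, rng):
        groups = [rng.standard_normal(n) + mu for n, mu in ((20, 0.0), (25, 0.4), (15, -0.2))]
        F, _, _, p = anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [len(g) for g in groups],
        )
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0, 2.0], [0.5, 0.5], [1, 10])


def test_compare_groups_stacks_all_inference_layers(rng):
    X = rng.standard_normal((40, 12))
    X[20:, :2] += 2.0
    y = np.repeat(["HC", "PKD"], 20)
    comp = compare_groups(
        X, y, n_perm=200, robustness=RobustnessConfig(n_replicates=20), seed=3
    )
    assert comp.significant[:2].all()
    assert comp.robust[:2].all()
    assert (comp.p_perm >= 1 / 201).all()
    assert comp.significant.sum() <= 4
    df = comp.to_frame(feature_names=[f"f{i}" for i in range(12)])
    assert set(["feature", "t", "p_perm", "p_fdr", "significant", "robust"]) <= set(df.columns)
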