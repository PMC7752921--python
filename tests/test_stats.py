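"""Accuracy measures, Wilcoxon/KL/KS comparisons, coefficient inference."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

import dtdecode as dd


class TestPredictionMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.uniform(17, 90, 10)
        m = dd.prediction_metrics(y, y, p_model=2)
        assert m.mae == 0.0 and m.rmse == 0.0
        assert m.r_squared == pytest.approx(1.0)
        assert m.pearson_r == pytest.approx(1.0)
        assert "objective2" in m.undefined  # zero-variance errors

    def test_constant_prediction_hand_example(self):
        m = dd.prediction_metrics([1, 2, 3], [2, 2, 2], p_model=1)
        assert m.mae == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(math.sqrt(2 / 3))
        assert m.r_squared == pytest.approx(0.0)
        assert "pearson_r" in m.undefined

    def test_objective2_hand_example(self):
        m = dd.prediction_metrics([1, 2, 3], [3, 2, 1], p_model=1)
        # errors (-2, 0, 2) are perfectly rank-correlated with y
        assert m.objective2 == pytest.approx(1.0)

    def test_constant_target_flags_correlations(self, rng):
        m = dd.prediction_metrics([5.0, 5.0, 5.0], rng.normal(size=3), 1)
        for field in ("r_squared", "pearson_r", "spearman_r", "objective2"):
            assert field in m.undefined

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(20):
            y = rng.normal(size=15)
            pred = rng.normal(size=15)
            m = dd.prediction_metrics(y, pred, p_model=3)
            assert m.mae <= m.rmse + 1e-12

    def test_adjusted_r2_formula(self, rng):
        y = rng.normal(size=30)
        pred = y + rng.normal(0, 0.5, 30)
        m = dd.prediction_metrics(y, pred, p_model=4)
        expected = 1 - (1 - m.r_squared) * 29 / (30 - 4 - 1)
        assert m.adj_r_squared == pytest.approx(expected)

    def test_spearman_invariant_under_dt(self, rng):
        y = rng.uniform(17, 90, 40)
        pred = rng.normal(50, 15, 40)
        reference = rng.uniform(17, 90, 160)
        transformed = dd.distributional_transform(pred, reference)
        m_raw = dd.prediction_metrics(y, pred, 5)
        m_dt = dd.prediction_metrics(y, transformed, 5)
        assert m_dt.spearman_r == pytest.approx(m_raw.spearman_r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dd.prediction_metrics([1, 2, 3], [1, 2])


def exact_signed_rank_p(d):
    """Exhaustive sign-flip enumeration of the signed-rank null (no ties)."""
    d = np.asarray(d, float)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    stats = [np.asarray(signs) @ ranks
             for signs in itertools.product([0, 1], repeat=d.size)]
    extreme = sum(1 for w in stats if abs(w - mu) >= abs(w_obs - mu) - 1e-9)
    return extreme / len(stats)


class TestWilcoxon:
    def test_identical_methods(self, rng):
        y = rng.normal(size=20)
        pred = rng.normal(size=20)
        z, p = dd.wilcoxon_ae_comparison(y, pred, pred)
        assert (z, p) == (0.0, 1.0)

    def test_sign_convention_better_method_negative_z(self, rng):
        y = rng.uniform(17, 90, 30)
        pred_b = y + rng.normal(0, 5, 30)
        z, p = dd.wilcoxon_ae_comparison(y, y, pred_b)  # method A is exact
        assert z < 0
        assert p < 0.001
        # and the reverse comparison flips the sign
        z_rev, _ = dd.wilcoxon_ae_comparison(y, pred_b, y)
        assert z_rev == pytest.approx(-z)

    def test_normal_approximation_close_to_exact_enumeration(self, rng):
        for _ in range(5):
            n = int(rng.integers(8, 13))
            y = rng.normal(size=n)
            a = y + rng.normal(0, 1, n)
            b = y + rng.normal(0, 1.5, n)
            d = np.abs(y - a) - np.abs(y - b)
            z, p_approx = dd.wilcoxon_ae_comparison(y, a, b, exact_max_n=0)
            p_exact = exact_signed_rank_p(d)
            assert abs(p_approx - p_exact) < 0.05

    def test_exact_path_matches_enumeration(self, rng):
        n = 10
        y = rng.normal(size=n)
        a = y + rng.normal(0, 1, n)
        b = y + rng.normal(0, 2, n)
        _, p = dd.wilcoxon_ae_comparison(y, a, b)  # n <= 25 -> exact
        d = np.abs(y - a) - np.abs(y - b)
        assert p == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_z_matches_scipy_approximation(self, rng):
        y = rng.normal(size=60)
        a = y + rng.normal(0, 1, 60)
        b = y + rng.normal(0, 1.2, 60)
        z, p = dd.wilcoxon_ae_comparison(y, a, b)
        d = np.abs(y - a) - np.abs(y - b)
        res = scipy.stats.wilcoxon(d, method="approx", correction=True)
        assert abs(z) == pytest.approx(abs(res.zstatistic), abs=1e-9)
        assert p == pytest.approx(res.pvalue, abs=1e-9)


class TestEmpiricalKL:
    def test_identical_samples_give_zero(self, rng):
        x = rng.uniform(17, 90, 200)
        for width in (0.5, 1.0, 5.0):
            assert dd.empirical_kl(x, x, bin_width=width) == 0.0

    def test_two_bin_closed_form(self):
        actual = [0.5, 0.5, 1.5, 1.5]        # p = (1/2, 1/2)
        predicted = [0.5, 1.5, 1.5, 1.5]     # q = (1/4, 3/4)
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert dd.empirical_kl(actual, predicted) == pytest.approx(expected)
        assert expected == pytest.approx(0.1438, abs=5e-5)

    def test_disjoint_support_large_finite_and_monotone_in_epsilon(self):
        actual = np.linspace(20, 30, 50)
        predicted = np.linspace(60, 70, 50)
        kl = dd.empirical_kl(actual, predicted)
        assert np.isfinite(kl) and kl > 1.0
        # duplicating both samples keeps the histograms but halves epsilon,
        # so the divergence grows (monotone in 1/epsilon)
        kl_bigger = dd.empirical_kl(np.repeat(actual, 2),
                                    np.repeat(predicted, 2))
        assert kl_bigger > kl

    def test_non_negative(self, rng):
        for _ in range(10):
            a = rng.normal(50, 10, 60)
            b = rng.normal(55, 15, 80)
            assert dd.empirical_kl(a, b) >= 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dd.empirical_kl([], [1.0])


def brute_force_ks_D(a, b):
    """sup over all sample points of |F_a - F_b|."""
    points = np.concatenate([a, b])
    return max(abs((a <= t).mean() - (b <= t).mean()) for t in points)


class TestKS:
    def test_identical_samples(self, rng):
        x = rng.normal(size=50)
        D, p = dd.ks_two_sample(x, x)
        assert (D, p) == (0.0, 1.0)

    def test_disjoint_ranges_give_D_one(self, rng):
        D, _ = dd.ks_two_sample(rng.uniform(0, 1, 30), rng.uniform(5, 6, 40))
        assert D == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(5, 40)))
            b = rng.normal(0.5, 1.2, size=int(rng.integers(5, 40)))
            D, _ = dd.ks_two_sample(a, b)
            assert D == pytest.approx(brute_force_ks_D(a, b), abs=1e-12)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dd.ks_two_sample([1.0], [1.0, 2.0])


class TestCoefficientInference:
    def test_intercept_only_closed_form(self, rng):
        y = rng.normal(size=40)
        [ci] = dd.coefficient_inference(np.ones((40, 1)), y)
        sigma = math.sqrt(((y - y.mean()) ** 2).sum() / 39)
        assert ci.se == pytest.approx(sigma / math.sqrt(40))

    def test_90ci_uses_normal_quantile_1_645(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        for ci in dd.coefficient_inference(X, y, alpha=0.10):
            half = (ci.ci_upper - ci.ci_lower) / 2
            assert half == pytest.approx(1.6449 * ci.se, rel=1e-4)
            assert ci.ci_lower <= ci.estimate <= ci.ci_upper

    def test_intervals_widen_as_alpha_decreases(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        widths = []
        for alpha in (0.2, 0.1, 0.01):
            cis = dd.coefficient_inference(X, y, alpha=alpha)
            widths.append(cis[0].ci_upper - cis[0].ci_lower)
        assert widths[0] < widths[1] < widths[2]

    def test_significance_tiers(self, rng):
        n = 500
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n),
                             np.ones(n)])
        y = 5.0 * X[:, 0] + 0.0 * X[:, 1] + rng.normal(size=n)
        cis = dd.coefficient_inference(X, y)
        assert cis[0].tier == "p<0.05/p_total"  # overwhelming effect
        assert cis[1].tier == "ns"

    def test_n_not_greater_than_p_rejected(self, rng):
        with pytest.raises(ValueError):
            dd.coefficient_inference(rng.normal(size=(3, 3)),
                                     rng.normal(size=3))

    def test_matches_statsmodels_ols(self, rng):
        """Independent cross-check of estimates and standard errors."""
        import statsmodels.api as sm
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -0.5, 2.0]) + rng.normal(size=60)
        ours = dd.coefficient_inference(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose([c.estimate for c in ours], ref.params,
                                   atol=1e-10)
        np.testing.assert_allclose([c.se for c in ours], ref.bse, atol=1e-10)
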