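"""Statistical operations checked against independent from-scratch oracles:
a covariance/SD Pearson formula, a numerically integrated normal tail for
the Fisher R-to-Z p-value, and algebraic OLS identities."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from temporient import (SyntheticSpec, correlation_report,
                        fisher_r_to_z_test, fit_linear_regression,
                        generate_user_cohort, pearson_r, profile_users,
                        standardized_frequency_curve)
from temporient.association import UNI_DIMENSIONS


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def oracle_normal_two_tail(z):
    """2 * integral of the standard normal pdf from |z| to infinity."""
    pdf = lambda t: math.exp(-t * t / 2.0) / math.sqrt(2.0 * math.pi)
    tail, _ = quad(pdf, abs(z), np.inf, epsabs=1e-14, epsrel=1e-14)
    return 2.0 * tail


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(1.0, 11.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(1.0, 11.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        assert pearson_r(x, y) == pytest.approx(oracle_pearson(x, y),
                                                abs=1e-10)

    def test_oracle_on_random_inputs(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.3 * x
            assert pearson_r(x, y) == pytest.approx(
                oracle_pearson(list(x), list(y)), abs=1e-10)

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson_r(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-10)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherRtoZ:
    def test_zero_r_gives_p_one(self):
        z, p_raw, p_bonf = fisher_r_to_z_test(0.0, 50)
        assert z == 0.0
        assert p_raw == pytest.approx(1.0)

    def test_matches_integrated_normal_tail(self):
        z, p_raw, _ = fisher_r_to_z_test(0.5, 100, 1)
        zstat = math.atanh(0.5) * math.sqrt(97)
        assert p_raw == pytest.approx(oracle_normal_two_tail(zstat),
                                      abs=1e-10)

    def test_oracle_on_random_r_n(self, rng):
        for _ in range(20):
            r = float(rng.uniform(-0.95, 0.95))
            n = int(rng.integers(5, 500))
            z, p_raw, _ = fisher_r_to_z_test(r, n)
            assert z == pytest.approx(math.atanh(r), abs=1e-12)
            zstat = math.atanh(r) * math.sqrt(n - 3)
            assert p_raw == pytest.approx(oracle_normal_two_tail(zstat),
                                          abs=1e-10)

    def test_bonferroni_cap(self):
        # a raw p around 0.3 multiplied by 10 tests caps at 1
        r, n = 0.15, 50
        _, p_raw, p_bonf = fisher_r_to_z_test(r, n, 10)
        assert p_raw * 10 > 1.0
        assert p_bonf == 1.0

    def test_degenerate_unit_r(self):
        z, p_raw, p_bonf = fisher_r_to_z_test(1.0, 10)
        assert math.isinf(z) and p_raw == 0.0 and p_bonf == 0.0

    def test_p_monotone_in_abs_r_and_n(self):
        ps = [fisher_r_to_z_test(r, 50)[1] for r in (0.1, 0.3, 0.5, 0.7)]
        assert ps == sorted(ps, reverse=True)
        pn = [fisher_r_to_z_test(0.3, n)[1] for n in (10, 50, 200, 1000)]
        assert pn == sorted(pn, reverse=True)


class TestLinearRegression:
    def test_through_origin(self):
        x = np.arange(1.0, 8.0)
        slope, intercept, r = fit_linear_regression(x, 3.0 * x)
        assert slope == pytest.approx(3.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-10)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_slope_sd_identity(self, rng):
        # slope * SD(x) / SD(y) equals the Pearson coefficient
        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        slope, _, r = fit_linear_regression(x, y)
        assert slope * x.std(ddof=1) / y.std(ddof=1) == pytest.approx(
            r, abs=1e-10)
        assert r == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_centering_x_shifts_only_intercept(self, rng):
        x = rng.standard_normal(30) + 5.0
        y = 2.0 * x + rng.standard_normal(30)
        s1, i1, _ = fit_linear_regression(x, y)
        s2, i2, _ = fit_linear_regression(x - x.mean(), y)
        assert s2 == pytest.approx(s1, abs=1e-10)
        assert i2 == pytest.approx(i1 + s1 * x.mean(), abs=1e-8)

    def test_constant_x_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestSmoothedCurve:
    @staticmethod
    def _cohort(n=60, seed=0):
        spec = SyntheticSpec(n_users=n, n_tweets_per_user=20, seed=seed)
        tweets, attrs = generate_user_cohort(spec)
        return profile_users(tweets, labels="gold"), attrs

    def test_linear_trend_reproduced(self):
        profiles, attrs = self._cohort()
        # plant a noiseless linear trend: dimension = 2*age + 3, so the
        # smoother's target is an exact line it must reproduce
        import pandas as pd
        ages = np.arange(len(profiles), dtype=float)
        attrs = pd.DataFrame({"user_id": attrs["user_id"], "age": ages})
        for p, a in zip(profiles, ages):
            p.uni["past"] = 2.0 * a + 3.0
        curve = standardized_frequency_curve(profiles, attrs, "age",
                                             "uni_past", span=0.5)
        interior = slice(5, -5)
        assert np.allclose(curve.smoothed[interior],
                           curve.standardized[interior], atol=1e-6)

    def test_standardization_and_sorted_grid(self):
        profiles, attrs = self._cohort(seed=3)
        curve = standardized_frequency_curve(profiles, attrs, "age",
                                             "uni_future")
        assert curve.standardized.mean() == pytest.approx(0.0, abs=1e-9)
        assert curve.standardized.std() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(curve.attribute) >= 0)

    def test_constant_dimension_is_error(self):
        profiles, attrs = self._cohort(n=20)
        for p in profiles:
            p.uni["past"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            standardized_frequency_curve(profiles, attrs, "age", "uni_past")

    def test_too_few_users_is_error(self):
        profiles, attrs = self._cohort(n=20)
        with pytest.raises(ValueError, match=">= 10"):
            standardized_frequency_curve(profiles[:5], attrs, "age",
                                         "uni_past")


class TestCorrelationReport:
    def test_uni_dimensions_one_attribute_counts(self):
        spec = SyntheticSpec(n_users=40, n_tweets_per_user=20, seed=1)
        tweets, attrs = generate_user_cohort(spec)
        profiles = profile_users(tweets, labels="gold")
        results = correlation_report(profiles, attrs,
                                     dimensions=UNI_DIMENSIONS)
        assert len(results) == 3
        # Bonferroni family = the three computed pairs
        for res in results:
            assert res.p_bonferroni == pytest.approx(
                min(1.0, res.p_raw * 3), abs=1e-12)

    def test_planted_correlation_recovered(self):
        spec = SyntheticSpec(n_users=500, n_tweets_per_user=25,
                             attribute_correlations={"age": ("past", 0.5)},
                             seed=21)
        tweets, attrs = generate_user_cohort(spec)
        profiles = profile_users(tweets, labels="gold")
        results = correlation_report(profiles, attrs)
        by_dim = {r.tp_dimension: r for r in results}
        assert 0.4 <= by_dim["uni_past"].r <= 0.6

    def test_undefined_bi_dropped_pairwise(self):
        spec = SyntheticSpec(n_users=30, n_tweets_per_user=4, seed=2)
        tweets, attrs = generate_user_cohort(spec)
        profiles = profile_users(tweets, labels="gold")
        # with 4 tweets/user some users lack a class entirely
        assert any(p.bi[("present", "neutral")] is None for p in profiles)
        results = correlation_report(profiles, attrs)
        uni_n = {r.tp_dimension: r.n for r in results
                 if r.tp_dimension.startswith("uni")}
        bi_n = [r.n for r in results if r.tp_dimension.startswith("bi")]
        assert all(n == 30 for n in uni_n.values())
        # pairwise deletion shrinks n for dimensions with undefined entries
        assert all(n <= 30 for n in bi_n)
        present_n = {r.n for r in results
                     if r.tp_dimension.startswith("bi_present")}
        assert all(n < 30 for n in present_n)

    def test_empty_join_is_fatal(self):
        import pandas as pd
        spec = SyntheticSpec(n_users=10, n_tweets_per_user=10, seed=0)
        tweets, attrs = generate_user_cohort(spec)
        profiles = profile_users(tweets, labels="gold")
        alien = pd.DataFrame({"user_id": ["zz1", "zz2"],
                              "age": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty join"):
            correlation_report(profiles, alien)
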