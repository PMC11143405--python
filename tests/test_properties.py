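"""Moments, series expansion, shape measures, residual life, order statistics."""

import math

import numpy as np
import pytest
from scipy import integrate

from ollged import (
    SeriesTruncationError,
    cdf,
    galton_skewness,
    mean_inactivity_time,
    mean_residual_life,
    mean_variance,
    mgf,
    moment_quadrature,
    moment_series,
    moors_kurtosis,
    order_statistic_moment,
    order_statistic_pdf,
    pdf,
    quantile,
    rvs,
    series_cdf,
    series_coeffs,
    shape_summary,
)

#: parameter points where the truncated series expansion is numerically
#: faithful (gamma = 1 keeps the quotient series benign); elsewhere the
#: rearrangement in powers of 1 - e^{-lambda x} diverges and the machinery
#: must signal truncation failure
SERIES_OK = [(1.0, 1.0, 1.0), (2.0, 1.0, 1.0), (1.0, 2.0, 1.0), (1.0, 3.0, 1.0), (1.0, 2.5, 1.0)]
SERIES_FAIL = [(1.0, 2.0, 2.0), (1.0, 1.5, 0.8), (1.5, 1.5, 1.5)]


class TestSeriesCoeffs:
    def test_exponential_case_is_exact(self):
        sc = series_coeffs((1, 1, 1), K=12)
        expect_a = np.zeros(13)
        expect_a[1] = 1.0
        np.testing.assert_allclose(sc.a, expect_a, atol=1e-12)
        expect_star = np.zeros(13)
        expect_star[0], expect_star[1] = 1.0, -1.0
        np.testing.assert_allclose(sc.a_star, expect_star, atol=1e-12)
        np.testing.assert_allclose(sc.c, expect_a, atol=1e-12)
        assert sc.c[0] == sc.a[0] / sc.b[0]

    def test_quotient_times_denominator_recovers_numerator(self):
        # polynomial-division oracle at z = 0.7 for (1, 2, 2)
        sc = series_coeffs((1, 2, 2), K=40, validate=False)
        z = 0.7
        lhs = np.polynomial.polynomial.polyval(z, np.convolve(sc.c, sc.b)[: sc.K + 1])
        rhs = np.polynomial.polynomial.polyval(z, sc.a)
        assert lhs == pytest.approx(rhs, abs=1e-8)

    @pytest.mark.parametrize("params", SERIES_OK)
    def test_series_cdf_matches_exact_cdf(self, params):
        sc = series_coeffs(params, K=40, tail_tol=1e-6)
        q = np.linspace(0.01, 0.99, 21)
        x = quantile(q, params)
        np.testing.assert_allclose(series_cdf(x, params, sc), q, atol=1e-6)

    @pytest.mark.parametrize("params", SERIES_FAIL)
    def test_divergent_rearrangement_signals_truncation_failure(self, params):
        with pytest.raises(SeriesTruncationError):
            series_coeffs(params, K=40, tail_tol=1e-6)

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            series_coeffs((1, 1, 1), K=0)


class TestMoments:
    def test_exponential_moments_exact(self):
        assert moment_quadrature(1, (1, 1, 1)) == pytest.approx(1.0, abs=1e-9)
        assert moment_quadrature(2, (1, 1, 1)) == pytest.approx(2.0, abs=1e-8)

    def test_mean_variance_unit_exponential(self):
        m, v = mean_variance((1, 1, 1))
        assert m == pytest.approx(1.0, abs=1e-8)
        assert v == pytest.approx(1.0, abs=1e-7)

    def test_mean_variance_tabulated_point(self):
        # (lambda, alpha, gamma) = (1, 2, 2): 1.3079 / 0.3066 at 4 dp
        m, v = mean_variance((1, 2, 2))
        assert m == pytest.approx(1.3079, abs=1e-4)
        assert v == pytest.approx(0.3066, abs=1e-4)

    def test_generalized_exponential_mean_closed_form(self):
        # E X = (psi(alpha+1) - psi(1)) / lambda for gamma = 1
        from scipy.special import digamma

        for lam, alpha in [(1.0, 2.0), (0.5, 3.5), (2.0, 0.7)]:
            expect = (digamma(alpha + 1) - digamma(1.0)) / lam
            assert moment_quadrature(1, (lam, alpha, 1.0)) == pytest.approx(expect, rel=1e-8)

    def test_variance_nonnegative_on_grid(self):
        for params in [(0.2, 0.2, 0.2), (1, 5, 0.3), (3, 0.4, 2)]:
            _, v = mean_variance(params)
            assert v >= 0

    @pytest.mark.parametrize("params", SERIES_OK)
    @pytest.mark.parametrize("r", [1, 2])
    def test_series_moment_agrees_with_quadrature(self, params, r):
        mq = moment_quadrature(r, params)
        ms = moment_series(r, params, K=40)
        assert ms == pytest.approx(mq, rel=1e-4)

    def test_series_moment_propagates_truncation_failure(self):
        with pytest.raises(SeriesTruncationError):
            moment_series(1, (1, 2, 2), K=40)

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            moment_quadrature(0, (1, 1, 1))


class TestMgf:
    def test_at_zero_is_one(self):
        assert mgf(0.0, (1, 2, 2)) == pytest.approx(1.0, abs=1e-9)

    def test_exponential_mgf_closed_form(self):
        for lam, t in [(1.0, 0.3), (2.0, -1.0), (0.5, 0.2)]:
            assert mgf(t, (lam, 1, 1)) == pytest.approx(lam / (lam - t), rel=1e-8)

    def test_slope_at_zero_is_the_mean(self):
        h = 1e-5
        slope = (mgf(h, (1, 2, 2)) - mgf(-h, (1, 2, 2))) / (2 * h)
        assert slope == pytest.approx(moment_quadrature(1, (1, 2, 2)), abs=1e-4)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            mgf(1.0, (1, 1, 1))
        # heavy tail for gamma < 1: exists only for t < gamma*lambda
        with pytest.raises(ValueError):
            mgf(0.6, (1, 1, 0.5))


class TestOctileShapeMeasures:
    def test_exponential_closed_forms(self):
        # octiles of Exp(1) are -log(1 - i/8); both measures are gamma-free
        # algebra: S = ln(4/3)/ln 3, M = ln(21/5)... evaluated numerically
        q = -np.log1p(-np.arange(1, 8) / 8)
        expect_s = (q[5] + q[1] - 2 * q[3]) / (q[5] - q[1])
        expect_m = (q[6] - q[4] + q[2] - q[0]) / (q[5] - q[1])
        assert expect_s == pytest.approx(0.26185, abs=1e-5)
        assert expect_m == pytest.approx(1.30627, abs=1e-5)
        assert galton_skewness((1, 1, 1)) == pytest.approx(expect_s, rel=1e-9)
        assert moors_kurtosis((1, 1, 1)) == pytest.approx(expect_m, rel=1e-9)

    def test_bounds_on_grid(self):
        for params in [(0.2, 0.3, 0.4), (1, 1, 1), (2, 5, 0.5), (1, 0.2, 5)]:
            assert -1 < galton_skewness(params) < 1
            assert moors_kurtosis(params) > 0

    def test_skewness_decreasing_in_shapes_at_unit_scale(self):
        # along alpha = gamma = 1..5 the octile skewness decreases; the
        # octile kurtosis does NOT (it dips at alpha=2 and then climbs
        # toward its exponential-tail limit), so only boundedness is
        # asserted for it
        vals_s = [galton_skewness((1, a, a)) for a in (1, 2, 3, 4, 5)]
        assert all(np.diff(vals_s) < 0)
        vals_m = [moors_kurtosis((1, a, a)) for a in (1, 2, 3, 4, 5)]
        assert all(1.29 < m < 1.31 for m in vals_m)

    def test_shape_summary_bundles_consistently(self):
        s = shape_summary((1, 2, 2))
        assert s.mean == pytest.approx(1.3079, abs=1e-4)
        assert s.galton_skewness == pytest.approx(galton_skewness((1, 2, 2)), rel=1e-12)


class TestResidualLife:
    def test_exponential_memorylessness(self):
        for t in (0.0, 1.0, 5.0):
            assert mean_residual_life(t, (2, 1, 1)) == pytest.approx(0.5, rel=1e-7)

    def test_at_zero_equals_the_mean(self):
        assert mean_residual_life(0.0, (1, 2, 2)) == pytest.approx(
            mean_variance((1, 2, 2))[0], abs=1e-8
        )

    def test_decreasing_under_increasing_hazard(self):
        # GE sub-model with alpha > 1 has a monotone increasing hazard,
        # hence a decreasing mean residual life; with gamma > 1 the hazard
        # overshoots its limit gamma*lambda and the MRL dips below
        # 1/(gamma*lambda) before climbing back, so it is checked only for
        # the monotone-hazard regime
        ts = np.linspace(0, 3, 7)
        vals = [mean_residual_life(t, (1, 3, 1)) for t in ts]
        assert all(np.diff(vals) < 0)
        late = [mean_residual_life(t, (1, 3, 3)) for t in (2.0, 3.0, 6.0)]
        assert all(v < 1 / 3 + 0.02 for v in late)

    def test_inactivity_time_bounded_by_t(self):
        for t in (0.5, 1.0, 3.0):
            mit = mean_inactivity_time(t, (1, 2, 0.7))
            assert 0 < mit < t

    def test_inactivity_two_route_identity(self):
        # integral of G over (0,t) / G(t) versus direct E[t - X | X <= t]
        params, t = (1, 1, 1), 1.0
        direct, _ = integrate.quad(lambda x: (t - x) * pdf(x, params), 0, t, epsabs=1e-12)
        direct /= cdf(t, params)
        assert mean_inactivity_time(t, params) == pytest.approx(direct, abs=1e-8)

    def test_domain_guards(self):
        with pytest.raises(ValueError):
            mean_inactivity_time(0.0, (1, 1, 1))
        with pytest.raises(ValueError):
            mean_residual_life(-1.0, (1, 1, 1))


class TestOrderStatistics:
    def test_single_observation_reduces_to_pdf(self):
        x = np.linspace(0.1, 5, 20)
        np.testing.assert_allclose(
            order_statistic_pdf(x, 1, 1, (1, 1.5, 0.7)), pdf(x, (1, 1.5, 0.7)), rtol=1e-12
        )

    def test_minimum_of_exponentials(self):
        x = np.linspace(0.05, 3, 20)
        m = 5
        np.testing.assert_allclose(
            order_statistic_pdf(x, 1, m, (1, 1, 1)), m * np.exp(-m * x), rtol=1e-10
        )

    def test_density_normalizes(self):
        val, _ = integrate.quad(
            lambda x: order_statistic_pdf(x, 2, 5, (1, 1.5, 0.7)), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-7)

    def test_mixture_identity(self):
        # averaging the order-statistic densities over ranks recovers g
        x = np.linspace(0.2, 4, 9)
        n = 4
        avg = np.mean([order_statistic_pdf(x, j, n, (1, 2, 0.8)) for j in range(1, n + 1)], axis=0)
        np.testing.assert_allclose(avg, pdf(x, (1, 2, 0.8)), rtol=1e-9)

    def test_exponential_moment_closed_forms(self):
        assert order_statistic_moment(1, 1, 4, (1, 1, 1)) == pytest.approx(0.25, rel=1e-7)
        # max of two Exp(1): 1 + 1/2
        assert order_statistic_moment(1, 2, 2, (1, 1, 1)) == pytest.approx(1.5, rel=1e-7)

    def test_moment_against_monte_carlo(self):
        params, j, n = (1, 2, 2), 3, 5
        draws = rvs(100_000, params, seed=77).reshape(20_000, 5)
        stat = np.sort(draws, axis=1)[:, j - 1]
        se = stat.std(ddof=1) / math.sqrt(stat.size)
        assert order_statistic_moment(1, j, n, params) == pytest.approx(stat.mean(), abs=3 * se)

    def test_rank_validation(self):
        with pytest.raises(ValueError):
            order_statistic_pdf(1.0, 0, 5, (1, 1, 1))
        with pytest.raises(ValueError):
            order_statistic_moment(1, 6, 5, (1, 1, 1))
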