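"""Estimator correctness against independent oracles.

OLS is checked against a direct normal-equations solve; the Newey-West HAC
covariance against statsmodels' sandwich implementation and the White (HC0)
limit; Cochrane-Orcutt against a one-step GLS with the true rho; and the
AR(1) exact likelihood against both a dense Toeplitz-covariance multivariate
normal density and statsmodels' Kalman-filter SARIMAX.
"""

import numpy as np
import pytest
import statsmodels.api as sm
import statsmodels.stats.sandwich_covariance as sw
from scipy.linalg import toeplitz
from scipy.stats import multivariate_normal

from scedmed import (
    EstimationError,
    build_design,
    estimate_rho,
    fit_ar1_ml,
    fit_equations,
    fit_fgls_cochrane_orcutt,
    fit_method,
    fit_newey_west,
    fit_ols,
    newey_west_auto_lag,
    newey_west_cov,
)
from scedmed.estimators import _ar1_full_loglik

from conftest import make_series


def _design(n, seed=0):
    s = make_series(n=n, seed=seed)
    return build_design(s), s


def _coefs(fit):
    return np.array(list(fit.coef.values()))


class TestOLS:
    def test_noiseless_response_recovered_exactly(self):
        d, _ = _design(12)
        y = 1.0 + 0.5 * d.column("time") + 2.0 * d.column("phase") \
            + 0.2 * d.column("phase_time")
        fit = fit_ols(d, y)
        np.testing.assert_allclose(_coefs(fit), [1.0, 0.5, 2.0, 0.2], atol=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self, rng):
        d, _ = _design(20, seed=1)
        y = rng.normal(size=20)
        fit = fit_ols(d, y)
        x = d.x
        beta = np.linalg.solve(x.T @ x, x.T @ y)  # independent solve
        np.testing.assert_allclose(_coefs(fit), beta, rtol=1e-10)
        s2 = np.sum((y - x @ beta) ** 2) / (20 - 4)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(x.T @ x)))
        np.testing.assert_allclose(list(fit.se.values()), se, rtol=1e-10)

    def test_response_equal_to_time_column(self):
        d, _ = _design(10)
        fit = fit_ols(d, d.column("time"))
        np.testing.assert_allclose(_coefs(fit), [0, 1, 0, 0], atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(EstimationError, match="singular"):
            fit_ols(x, np.arange(10.0))

    def test_missing_response_rejected(self, series20):
        series20.m[3] = np.nan
        with pytest.raises(EstimationError, match="missing"):
            fit_equations(series20, "OLS")


class TestNeweyWest:
    def test_lag_zero_equals_white_hc0(self, rng):
        d, _ = _design(30, seed=2)
        y = rng.normal(size=30)
        ols = fit_ols(d, y)
        x = d.x
        cov0 = newey_west_cov(x, ols.residuals, max_lag=0)
        bread = np.linalg.inv(x.T @ x)
        hc0 = bread @ (x.T @ np.diag(ols.residuals**2) @ x) @ bread
        np.testing.assert_allclose(cov0, hc0, rtol=1e-10)

    @pytest.mark.parametrize("lag", [0, 1, 3, 6])
    def test_matches_statsmodels_hac(self, lag, rng):
        d, s = _design(40, seed=3)
        res = sm.OLS(s.m, d.x).fit()
        ref = sw.cov_hac_simple(res, nlags=lag, use_correction=False)
        mine = newey_west_cov(d.x, res.resid, max_lag=lag)
        np.testing.assert_allclose(mine, ref, rtol=1e-9)

    def test_point_estimates_identical_to_ols(self, rng):
        d, s = _design(30, seed=4)
        np.testing.assert_array_equal(
            _coefs(fit_newey_west(d, s.m)), _coefs(fit_ols(d, s.m))
        )

    def test_psd_on_random_instances(self, rng):
        for _ in range(10):
            x = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
            e = rng.normal(size=25)
            cov = newey_west_cov(x, e, max_lag=4)
            assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_auto_lag_rule(self):
        assert newey_west_auto_lag(100) == 4
        assert newey_west_auto_lag(20) == 2

    def test_invalid_lag_rejected(self):
        with pytest.raises(ValueError, match="max_lag"):
            newey_west_cov(np.ones((5, 1)), np.ones(5), max_lag=5)

    def test_iid_large_sample_agrees_with_classical(self):
        n = 2000
        rng = np.random.default_rng(11)
        x = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = x @ [1.0, 2.0, -1.0] + rng.normal(size=n)
        ols = fit_ols(x, y)
        nw = fit_newey_west(x, y)
        ratio = np.array(list(nw.se.values())) / np.array(list(ols.se.values()))
        assert np.all(np.abs(ratio - 1.0) < 0.10)


class TestEstimateRho:
    def test_alternating_residuals_hand_value(self):
        assert estimate_rho([1, -1, 1, -1, 1, -1]) == pytest.approx(-5.0 / 6.0)

    def test_iid_residuals_near_zero(self):
        e = np.random.default_rng(5).standard_normal(10_000)
        assert abs(estimate_rho(e)) < 0.03

    def test_constant_residuals_clipped_in_long_limit(self):
        # (n-1)/n exceeds the stationarity clip once n is large
        assert estimate_rho(np.ones(5000)) == pytest.approx(0.999)
        assert estimate_rho(np.ones(50)) == pytest.approx(49 / 50)

    def test_all_zero_rejected(self):
        with pytest.raises(EstimationError, match="rho undefined"):
            estimate_rho(np.zeros(10))


class TestFGLS:
    def test_small_rho_first_pass_exit_returns_ols(self):
        # iid errors: when the OLS-residual rho is already below tol the
        # procedure exits on the first pass with the OLS solution
        s = make_series(n=50, rho=0.0, seed=7)
        d = build_design(s)
        ols = fit_ols(d, s.m)
        rho0 = abs(estimate_rho(ols.residuals))
        fgls = fit_fgls_cochrane_orcutt(d, s.m, tol=rho0 * 1.01 + 1e-12)
        np.testing.assert_allclose(_coefs(fgls), _coefs(ols), rtol=1e-12)
        assert fgls.converged

    def test_recovers_rho_half_large_n(self):
        s = make_series(n=5000, rho=0.5, seed=8)
        d = build_design(s)
        fit = fit_fgls_cochrane_orcutt(d, s.m)
        assert fit.rho_hat == pytest.approx(0.5, abs=0.05)
        np.testing.assert_allclose(_coefs(fit)[2:], [2.0, 0.2], atol=0.3)

    def test_forced_rho_equals_oracle_gls(self):
        s = make_series(n=60, rho=0.5, seed=9)
        d = build_design(s)
        fit = fit_fgls_cochrane_orcutt(d, s.m, rho_fixed=0.5)
        x, y = d.x, s.m
        xs, ys = x[1:] - 0.5 * x[:-1], y[1:] - 0.5 * y[:-1]
        beta = np.linalg.solve(xs.T @ xs, xs.T @ ys)  # one-step GLS oracle
        np.testing.assert_allclose(_coefs(fit), beta, rtol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_whitening_reduces_lag1_autocorrelation(self, seed):
        s = make_series(n=100, rho=0.8, seed=seed)
        d = build_design(s)
        ols = fit_ols(d, s.m)
        rho_before = estimate_rho(ols.residuals)
        fgls = fit_fgls_cochrane_orcutt(d, s.m)
        x, y = d.x, s.m
        xs, ys = x[1:] - fgls.rho_hat * x[:-1], y[1:] - fgls.rho_hat * y[:-1]
        starred_resid = ys - xs @ _coefs(fgls)
        assert abs(estimate_rho(starred_resid)) <= abs(rho_before) + 1e-12


class TestAR1ML:
    def test_loglik_matches_dense_toeplitz_oracle(self):
        for n, seed in [(20, 1), (50, 2)]:
            s = make_series(n=n, rho=0.6, seed=seed)
            d = build_design(s)
            fit = fit_ar1_ml(d, s.m)
            beta, rho, s2 = _coefs(fit), fit.rho_hat, fit.sigma2
            cov = s2 * toeplitz(rho ** np.arange(n)) / (1 - rho**2)
            oracle = multivariate_normal.logpdf(s.m, mean=d.x @ beta, cov=cov)
            assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_rho_zero_data_agrees_with_ols(self):
        s = make_series(n=2000, rho=0.0, seed=3)
        d = build_design(s)
        ar1 = fit_ar1_ml(d, s.m)
        ols = fit_ols(d, s.m)
        np.testing.assert_allclose(_coefs(ar1), _coefs(ols), atol=1e-3)

    def test_recovers_rho_09_large_n(self):
        s = make_series(n=5000, rho=0.9, seed=4)
        d = build_design(s)
        fit = fit_ar1_ml(d, s.m)
        assert fit.rho_hat == pytest.approx(0.9, abs=0.03)

    def test_matches_sarimax_kalman_filter(self):
        s = make_series(n=40, rho=0.5, seed=11)
        d = build_design(s)
        fit = fit_ar1_ml(d, s.m)
        ref = sm.tsa.SARIMAX(s.m, exog=d.x, order=(1, 0, 0), trend="n").fit(
            disp=0, cov_type="oim"
        )
        assert fit.loglik >= ref.llf - 1e-4  # same optimum (or better)
        np.testing.assert_allclose(_coefs(fit), ref.params[:4], atol=5e-3)
        assert fit.rho_hat == pytest.approx(ref.params[4], abs=5e-3)
        np.testing.assert_allclose(
            list(fit.se.values()), ref.bse[:4], rtol=0.05
        )

    def test_iid_limit_equals_gaussian_loglik(self):
        s = make_series(n=30, rho=0.0, seed=6)
        d = build_design(s)
        ols = fit_ols(d, s.m)
        beta = _coefs(ols)
        s2_ml = float(ols.residuals @ ols.residuals) / 30
        theta = np.concatenate([beta, [0.0, s2_ml]])
        iid_ll = np.sum(
            -0.5 * np.log(2 * np.pi * s2_ml) - ols.residuals**2 / (2 * s2_ml)
        )
        assert _ar1_full_loglik(theta, d.x, s.m) == pytest.approx(iid_ll, abs=1e-10)


class TestMethodAgreement:
    def test_all_methods_converge_on_iid_data_large_n(self):
        s = make_series(n=5000, rho=0.0, seed=10)
        d = build_design(s)
        fits = [fit_method(m, d, s.m) for m in ("OLS", "NW", "FGLS", "AR1")]
        ref = _coefs(fits[0])
        for f in fits[1:]:
            np.testing.assert_allclose(_coefs(f), ref, atol=0.02)

    def test_fit_equations_y_has_extra_coefficient(self, series20):
        m_fit, y_fit = fit_equations(series20, "OLS")
        assert set(m_fit.coef) == {"b0", "b1", "b2", "b3"}
        assert set(y_fit.coef) == {"b0", "b1", "b2", "b3", "b4"}

    def test_refuses_too_few_observed_per_phase(self):
        s = make_series(n=8, seed=0)
        s.m[:2] = np.nan
        with pytest.raises(EstimationError):
            fit_equations(s, "OLS")
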