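"""Piecewise-regression estimators with four autocorrelation-handling routes.

The mediation model for an AB single-case series is a pair of piecewise
regressions::

    M_t = b0 + b1*time_t + b2*phase_t + b3*phase_time_t            + e_t
    Y_t = b0 + b1*time_t + b2*phase_t + b3*phase_time_t + b4*M_t   + e_t

with errors that may follow a stationary AR(1) process
``e_t = rho*e_{t-1} + nu_t``.  Each equation can be fitted by:

``OLS``
    ordinary least squares with classical standard errors;
``NW``
    OLS coefficients with Newey-West heteroskedasticity- and
    autocorrelation-consistent (HAC) standard errors (Bartlett kernel);
``FGLS``
    feasible GLS via the iterative Cochrane-Orcutt procedure
    (quasi-differencing with an estimated lag-1 autocorrelation);
``AR1``
    exact Gaussian maximum likelihood of the regression-with-AR(1)-errors
    model with stationary initialization.

All four return a :class:`PiecewiseFit`; NW shares OLS's point estimates and
differs only in the covariance used for standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from statsmodels.tools.numdiff import approx_hess

from .sced_data import DesignMatrix, DegenerateDesignError, SCEDSeries, build_design

__all__ = [
    "PiecewiseFit",
    "EstimationError",
    "METHODS",
    "fit_ols",
    "fit_newey_west",
    "newey_west_cov",
    "newey_west_auto_lag",
    "estimate_rho",
    "fit_fgls_cochrane_orcutt",
    "fit_ar1_ml",
    "fit_method",
    "fit_equations",
]

METHODS = ("OLS", "NW", "FGLS", "AR1")

RHO_BOUND = 0.999
MIN_OBS_PER_PHASE = 3


class EstimationError(RuntimeError):
    """Estimation cannot proceed (rank deficiency, too few observations...)."""


@dataclass
class PiecewiseFit:
    """Result of fitting one piecewise-regression equation.

    ``coef``/``se`` are keyed b0..b3 (mediator equation) or b0..b4 (outcome
    equation, b4 being the mediator slope).  ``rho_hat`` is the estimated
    lag-1 error autocorrelation for FGLS/AR1 and None for OLS/NW;
    ``loglik`` is the exact Gaussian log-likelihood for AR1 and None
    otherwise.  ``residuals`` are on the original (untransformed) scale.
    """

    method: str
    equation: str  # "M" or "Y"
    coef: dict[str, float]
    se: dict[str, float]
    residuals: np.ndarray
    n_used: int
    rho_hat: float | None = None
    sigma2: float | None = None
    loglik: float | None = None
    converged: bool = True
    cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.equation not in ("M", "Y"):
            raise ValueError("equation must be 'M' or 'Y'")
        if set(self.se) != set(self.coef):
            raise ValueError("coef and se must share keys")
        if self.converged:
            # zero SEs are legitimate for exactly-interpolated (noiseless) data
            bad = [k for k, v in self.se.items() if not (np.isfinite(v) and v >= 0)]
            if bad:
                raise EstimationError(f"negative/non-finite SE for {bad}")
        if self.rho_hat is not None and not abs(self.rho_hat) < 1:
            raise EstimationError(f"|rho_hat| must be < 1, got {self.rho_hat}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f"b{i}" for i in range(len(self.coef)))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "equation": self.equation,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "rho_hat": None if self.rho_hat is None else float(self.rho_hat),
            "sigma2": None if self.sigma2 is None else float(self.sigma2),
            "loglik": None if self.loglik is None else float(self.loglik),
            "n_used": int(self.n_used),
            "converged": bool(self.converged),
        }


# ---------------------------------------------------------------------------
# regressor assembly
# ---------------------------------------------------------------------------


def _regressors(design, mediator=None):
    """(X, equation) for one equation; appending the mediator column makes it
    the outcome equation."""
    x = design.x if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if mediator is None:
        return x, "M"
    med = np.asarray(mediator, float)
    if med.shape != (x.shape[0],):
        raise ValueError("mediator length must match design rows")
    return np.column_stack([x, med]), "Y"


def _check_design(x: np.ndarray, y: np.ndarray, extra_df: int = 0) -> None:
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("response length must match design rows")
    if np.isnan(y).any() or np.isnan(x).any():
        raise EstimationError(
            "missing values in response/design; resolve missingness upstream"
        )
    if n < p + extra_df:
        raise EstimationError(f"need n >= {p + extra_df}, got n={n}")
    if np.linalg.matrix_rank(x) < p:
        raise EstimationError("singular (rank-deficient) design")


def _pack(method, equation, x, y, params, se, cov, **kw) -> PiecewiseFit:
    names = tuple(f"b{i}" for i in range(x.shape[1]))
    resid = y - x @ params
    return PiecewiseFit(
        method=method,
        equation=equation,
        coef=dict(zip(names, map(float, params))),
        se=dict(zip(names, map(float, se))),
        residuals=resid,
        n_used=x.shape[0],
        cov=cov,
        **kw,
    )


# ---------------------------------------------------------------------------
# OLS and Newey-West
# ---------------------------------------------------------------------------


def fit_ols(design, response, mediator=None) -> PiecewiseFit:
    """Ordinary least squares with classical SEs (sigma^2 (X'X)^-1, df n-p)."""
    x, equation = _regressors(design, mediator)
    y = np.asarray(response, float)
    _check_design(x, y, extra_df=1)
    res = sm.OLS(y, x).fit()
    return _pack(
        "OLS", equation, x, y, res.params, res.bse, np.asarray(res.cov_params()),
        sigma2=float(res.mse_resid),
    )


def newey_west_auto_lag(n: int) -> int:
    """Standard Newey-West truncation-lag rule floor(4 (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))


def newey_west_cov(design, residuals, max_lag: int | None = None) -> np.ndarray:
    """Bartlett-kernel HAC covariance of OLS coefficients.

    Lag weights are ``w_l = 1 - l/(L+1)`` over lags ``0..L``; ``max_lag=None``
    uses the automatic rule.  At ``max_lag=0`` this is the White
    heteroskedasticity-consistent (HC0) covariance.
    """
    x = design.x if isinstance(design, DesignMatrix) else np.asarray(design, float)
    e = np.asarray(residuals, float)
    n = x.shape[0]
    lag = newey_west_auto_lag(n) if max_lag is None else int(max_lag)
    if lag < 0 or lag >= n:
        raise ValueError(f"max_lag must be in [0, n), got {lag} with n={n}")
    xe = x * e[:, None]
    meat = xe.T @ xe  # lag-0 term
    for ell in range(1, lag + 1):
        w = 1.0 - ell / (lag + 1.0)
        gamma = xe[ell:].T @ xe[:-ell]
        meat += w * (gamma + gamma.T)
    bread = np.linalg.inv(x.T @ x)
    cov = bread @ meat @ bread
    return (cov + cov.T) / 2.0


def fit_newey_west(design, response, mediator=None, max_lag=None) -> PiecewiseFit:
    """OLS point estimates with Newey-West HAC standard errors."""
    ols = fit_ols(design, response, mediator)
    x, _ = _regressors(design, mediator)
    cov = newey_west_cov(x, ols.residuals, max_lag=max_lag)
    se = np.sqrt(np.diag(cov))
    fit = _pack(
        "NW", ols.equation, x, np.asarray(response, float),
        np.array(list(ols.coef.values())), se, cov, sigma2=ols.sigma2,
    )
    return fit


# ---------------------------------------------------------------------------
# lag-1 autocorrelation and Cochrane-Orcutt FGLS
# ---------------------------------------------------------------------------


def estimate_rho(residuals) -> float:
    """Lag-1 sample autocorrelation sum(e_t e_{t-1}) / sum(e_t^2), clipped to
    the open stationarity interval."""
    e = np.asarray(residuals, float)
    if e.size < 3:
        raise ValueError("need >= 3 residuals to estimate rho")
    denom = float(e @ e)
    if denom == 0.0:
        raise EstimationError("rho undefined: all residuals are zero")
    rho = float(e[1:] @ e[:-1]) / denom
    return float(np.clip(rho, -RHO_BOUND, RHO_BOUND))


def _quasi_difference(x, y, rho):
    return x[1:] - rho * x[:-1], y[1:] - rho * y[:-1]


def fit_fgls_cochrane_orcutt(
    design,
    response,
    mediator=None,
    tol: float = 1e-6,
    max_iter: int = 100,
    rho_fixed: float | None = None,
) -> PiecewiseFit:
    """Feasible GLS via the iterative Cochrane-Orcutt procedure.

    Alternates (i) residuals on the original scale from the current
    coefficients, (ii) lag-1 autocorrelation of those residuals, (iii) OLS on
    rho-quasi-differenced data (first observation dropped, all columns —
    including the intercept — transformed, so coefficients come back on the
    original scale).  Stops when rho changes by less than ``tol``.  SEs come
    from the final transformed regression.  ``rho_fixed`` skips estimation and
    performs a single GLS step at a known rho (diagnostic use).
    """
    x, equation = _regressors(design, mediator)
    y = np.asarray(response, float)
    _check_design(x, y, extra_df=2)

    if rho_fixed is not None:
        xs, ys = _quasi_difference(x, y, rho_fixed)
        res = sm.OLS(ys, xs).fit()
        return _pack(
            "FGLS", equation, x, y, res.params, res.bse, np.asarray(res.cov_params()),
            rho_hat=float(rho_fixed), sigma2=float(res.mse_resid), converged=True,
        )

    res = sm.OLS(y, x).fit()
    beta = res.params
    rho_prev = 0.0
    rho = estimate_rho(y - x @ beta)
    converged = abs(rho - rho_prev) < tol
    it = 0
    while not converged and it < max_iter:
        xs, ys = _quasi_difference(x, y, rho)
        res = sm.OLS(ys, xs).fit()
        beta = res.params
        rho_prev = rho
        rho = estimate_rho(y - x @ beta)
        converged = abs(rho - rho_prev) < tol
        it += 1
    if not converged:
        warnings.warn(
            f"Cochrane-Orcutt did not converge in {max_iter} iterations "
            f"(last |drho|={abs(rho - rho_prev):.2e})",
            RuntimeWarning,
        )
    return _pack(
        "FGLS", equation, x, y, beta, res.bse, np.asarray(res.cov_params()),
        rho_hat=rho, sigma2=float(res.mse_resid), converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# exact-ML regression with AR(1) errors
# ---------------------------------------------------------------------------


def _pw_whiten(x, y, rho):
    """Prais-Winsten whitening: the transformed model has iid innovations,
    including the stationary scaling sqrt(1-rho^2) of the first row."""
    c = np.sqrt(1.0 - rho * rho)
    xs = np.vstack([c * x[:1], x[1:] - rho * x[:-1]])
    ys = np.concatenate([c * y[:1], y[1:] - rho * y[:-1]])
    return xs, ys


def _profile_step(x, y, rho):
    """GLS coefficients, ML innovation variance and exact loglik at fixed rho."""
    xs, ys = _pw_whiten(x, y, rho)
    beta, _, _, _ = np.linalg.lstsq(xs, ys, rcond=None)
    resid = ys - xs @ beta
    n = y.size
    ssr = float(resid @ resid)
    sigma2 = max(ssr / n, 1e-300)
    # |Sigma| = sigma2^n / (1-rho^2) for the stationary AR(1) covariance
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * n \
        + 0.5 * np.log1p(-rho * rho)
    return beta, sigma2, loglik


def _ar1_full_loglik(theta, x, y):
    """Exact Gaussian loglik at theta = (beta..., rho, sigma2_nu)."""
    p = x.shape[1]
    beta, rho, sigma2 = theta[:p], theta[p], theta[p + 1]
    if not (abs(rho) < 1.0 and sigma2 > 0.0):
        return -np.inf
    xs, ys = _pw_whiten(x, y, rho)
    resid = ys - xs @ beta
    n = y.size
    return (
        -0.5 * n * np.log(2.0 * np.pi * sigma2)
        + 0.5 * np.log1p(-rho * rho)
        - float(resid @ resid) / (2.0 * sigma2)
    )


def fit_ar1_ml(design, response, mediator=None, grid_size: int = 41) -> PiecewiseFit:
    """Exact maximum likelihood for regression with stationary AR(1) errors.

    The Gaussian likelihood (initial error variance sigma2/(1-rho^2)) is
    concentrated over the coefficients and innovation variance, leaving a
    one-dimensional profile in rho that is scanned on a grid and polished by
    Brent's method.  SEs are the square roots of the diagonal of the inverse
    observed information (numerical Hessian of the exact log-likelihood at
    the optimum); a GLS-conditional covariance is the fallback when that
    Hessian is not invertible.
    """
    x, equation = _regressors(design, mediator)
    y = np.asarray(response, float)
    _check_design(x, y, extra_df=2)
    n, p = x.shape

    grid = np.linspace(-0.98, 0.98, grid_size)
    lls = np.array([_profile_step(x, y, r)[2] for r in grid])
    r0 = grid[int(np.argmax(lls))]
    lo = max(r0 - 0.06, -RHO_BOUND)
    hi = min(r0 + 0.06, RHO_BOUND)
    opt = minimize_scalar(
        lambda r: -_profile_step(x, y, r)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(np.clip(opt.x, -RHO_BOUND, RHO_BOUND))
    converged = bool(opt.success)
    if abs(rho) >= RHO_BOUND - 1e-9:
        warnings.warn("AR(1) rho estimate at stationarity bound", RuntimeWarning)
    beta, sigma2, loglik = _profile_step(x, y, rho)

    theta = np.concatenate([beta, [rho, sigma2]])
    se = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(theta, lambda t: -_ar1_full_loglik(t, x, y))
            cov_full = np.linalg.inv(hess)
        d = np.diag(cov_full)[:p]
        if np.all(np.isfinite(d)) and np.all(d > 0):
            se = np.sqrt(d)
            cov = cov_full[:p, :p]
    except np.linalg.LinAlgError:
        pass
    if se is None:  # fall back to GLS covariance at the fitted rho
        xs, _ = _pw_whiten(x, y, rho)
        cov = sigma2 * np.linalg.inv(xs.T @ xs)
        se = np.sqrt(np.diag(cov))

    return _pack(
        "AR1", equation, x, y, beta, se, cov,
        rho_hat=rho, sigma2=sigma2, loglik=float(loglik), converged=converged,
    )


# ---------------------------------------------------------------------------
# dispatch helpers
# ---------------------------------------------------------------------------

_FITTERS = {
    "OLS": fit_ols,
    "NW": fit_newey_west,
    "FGLS": fit_fgls_cochrane_orcutt,
    "AR1": fit_ar1_ml,
}


def fit_method(method: str, design, response, mediator=None, **kwargs) -> PiecewiseFit:
    """Fit one equation by name ('OLS', 'NW', 'FGLS' or 'AR1')."""
    try:
        fitter = _FITTERS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
    return fitter(design, response, mediator=mediator, **kwargs)


def fit_equations(
    series: SCEDSeries, method: str, anchor: int = 0, **kwargs
) -> tuple[PiecewiseFit, PiecewiseFit]:
    """Fit both piecewise equations of a complete series by one method.

    Refuses series with missing mediator/outcome values (handle missingness
    with multiple imputation upstream) or fewer than three observed occasions
    in either phase.
    """
    if series.has_missing():
        raise EstimationError(
            "series has missing values; use the multiple-imputation pipeline"
        )
    n_obs = series.n_observed()
    if n_obs.min() < MIN_OBS_PER_PHASE:
        raise DegenerateDesignError(
            f"need >= {MIN_OBS_PER_PHASE} observed occasions per phase, "
            f"got A={n_obs[0]}, B={n_obs[1]}"
        )
    design = build_design(series, anchor=anchor)
    m_fit = fit_method(method, design, series.m, **kwargs)
    y_fit = fit_method(method, design, series.y, mediator=series.m, **kwargs)
    return m_fit, y_fit
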