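"""Missing-data handling: MCAR amputation, chained-equation multiple
imputation, and Rubin's-rules pooling.

Missingness in single-case diaries is typically occasion-level: when the
participant skips a measurement occasion, both the mediator and the outcome
are unrecorded while the design variables (time, phase) remain known.
:func:`ampute_mcar` imposes exactly that mechanism.  :func:`impute_chained`
fills the holes by chained equations: each incomplete variable gets a
univariate Bayesian-linear imputation model on the design columns plus the
other variable, with predictive-mean matching (PMM) as the default draw —
an imputed cell is the observed value of a donor whose predicted mean is
close to the missing cell's predicted mean, so imputations stay in the
observed range.  Analyses are run per completed dataset and combined with
Rubin's rules: the pooled estimate is the mean, and the total variance adds
the between-imputation spread B to the mean within-imputation variance U,
T = U + (1 + 1/m) B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimationError, PiecewiseFit, fit_equations
from .sced_data import SCEDSeries, build_design

__all__ = [
    "ImputationSet",
    "PooledEstimate",
    "MIFit",
    "ampute_mcar",
    "impute_chained",
    "pool_rubin",
    "fit_with_mi",
]

DEFAULT_M = 100
DEFAULT_ITERATIONS = 5
DEFAULT_DONOR_POOL = 5
MAX_FIT_FAILURE_FRACTION = 0.2


@dataclass(frozen=True)
class ImputationSet:
    """m completed copies of one series; only originally-missing cells vary."""

    datasets: list
    iterations: int
    seed: int
    donor_pool: int

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (imputation_id, occasion, m, y) across all datasets."""
        rows = []
        for j, ds in enumerate(self.datasets):
            rows.append(
                pd.DataFrame(
                    {
                        "imputation_id": j,
                        "occasion": ds.occasion,
                        "m": ds.m,
                        "y": ds.y,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of one scalar estimate across imputations."""

    q_bar: float
    u_bar: float
    b_between: float
    t_total: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t_total))


def ampute_mcar(series: SCEDSeries, prop: float, seed=0) -> SCEDSeries:
    """Remove exactly round(prop*T) occasions completely at random, blanking
    the mediator and outcome jointly at each selected occasion.

    Refuses amputation patterns that leave fewer than three jointly-observed
    occasions in either phase, since the piecewise fit would be degenerate.
    """
    if not 0.0 <= prop < 1.0:
        raise ValueError("prop must be in [0, 1)")
    out = series.copy()
    t = series.n_occasions
    k = int(round(prop * t))
    if k == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drop = rng.choice(t, size=k, replace=False)
    out.m[drop] = np.nan
    out.y[drop] = np.nan
    n_obs = out.n_observed()
    if n_obs.min() < 3:
        raise EstimationError(
            f"amputation leaves fewer than 3 observed occasions in a phase "
            f"(A={n_obs[0]}, B={n_obs[1]})"
        )
    return out


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------


def _bayes_draw(x_obs, y_obs, rng):
    """Posterior parameter draw for the normal linear imputation model."""
    n, p = x_obs.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    if rank < p or n <= p + 1:
        raise np.linalg.LinAlgError("degenerate imputation model")
    resid = y_obs - x_obs @ beta_hat
    df = n - p
    sigma2_star = float(resid @ resid) / rng.chisquare(df)
    xtx_inv = np.linalg.inv(x_obs.T @ x_obs)
    chol = np.linalg.cholesky(sigma2_star * xtx_inv)
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_star, sigma2_star


def _impute_one_variable(x, target, miss, rng, engine, donor_pool):
    """One univariate imputation sweep; returns new values for `miss` cells."""
    obs = ~miss
    x_obs, y_obs = x[obs], target[obs]
    try:
        beta_hat, beta_star, sigma2_star = _bayes_draw(x_obs, y_obs, rng)
    except np.linalg.LinAlgError:
        warnings.warn(
            "degenerate predictor matrix in imputation sweep; "
            "falling back to unconditional mean + noise",
            RuntimeWarning,
        )
        mu, sd = float(y_obs.mean()), float(y_obs.std(ddof=1) or 1.0)
        return rng.normal(mu, sd, size=int(miss.sum()))
    if engine == "norm":
        return x[miss] @ beta_star + rng.normal(
            0.0, np.sqrt(sigma2_star), size=int(miss.sum())
        )
    # PMM (type-1 matching): observed units ranked by beta_hat predictions,
    # missing units by beta_star predictions; draw from the nearest donors.
    pred_obs = x_obs @ beta_hat
    pred_mis = x[miss] @ beta_star
    d = min(donor_pool, pred_obs.size)
    out = np.empty(pred_mis.size)
    for j, pm in enumerate(pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - pm), d - 1)[:d]
        out[j] = y_obs[nearest[rng.integers(d)]]
    return out


def impute_chained(
    series: SCEDSeries,
    m: int = DEFAULT_M,
    iterations: int = DEFAULT_ITERATIONS,
    seed=0,
    donor_pool: int = DEFAULT_DONOR_POOL,
    engine: str = "pmm",
    anchor: int = 0,
) -> ImputationSet:
    """Multiple imputation of the mediator and outcome by chained equations.

    The mediator model regresses on (time, phase, phase_time, outcome) and the
    outcome model on (time, phase, phase_time, mediator); each of the ``m``
    chains initializes missing cells from random observed values and runs
    ``iterations`` sweeps.  ``engine`` is 'pmm' (default, donor-pool
    predictive-mean matching) or 'norm' (normal-linear draws).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if engine not in ("pmm", "norm"):
        raise ValueError("engine must be 'pmm' or 'norm'")
    miss_m = np.isnan(series.m)
    miss_y = np.isnan(series.y)
    if not (miss_m.any() or miss_y.any()):
        datasets = [series.copy() for _ in range(m)]
        return ImputationSet(datasets, iterations, _seed_int(seed), donor_pool)
    n_complete = int((~miss_m & ~miss_y).sum())
    if n_complete < 5:
        raise EstimationError(
            f"need >= 5 complete occasions to fit imputation models, got {n_complete}"
        )

    design = build_design(series, anchor=anchor).x  # intercept,time,phase,phase_time
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        _seed_int(seed)
    )
    datasets = []
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        mm = series.m.copy()
        yy = series.y.copy()
        if miss_m.any():
            mm[miss_m] = rng.choice(series.m[~miss_m], size=int(miss_m.sum()))
        if miss_y.any():
            yy[miss_y] = rng.choice(series.y[~miss_y], size=int(miss_y.sum()))
        for _ in range(iterations):
            if miss_m.any():
                x_m = np.column_stack([design, yy])
                mm[miss_m] = _impute_one_variable(
                    x_m, mm, miss_m, rng, engine, donor_pool
                )
            if miss_y.any():
                x_y = np.column_stack([design, mm])
                yy[miss_y] = _impute_one_variable(
                    x_y, yy, miss_y, rng, engine, donor_pool
                )
        datasets.append(SCEDSeries(series.phase.copy(), mm, yy))
    return ImputationSet(datasets, iterations, _seed_int(seed), donor_pool)


def _seed_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return -1  # generator/SeedSequence passed in; no single int to report


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates and their squared SEs.

    q_bar is the mean estimate, u_bar the mean within-imputation variance,
    B the sample variance of the estimates, and the total variance
    T = u_bar + (1 + 1/m) B.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.size == 0 or q.shape != u.shape:
        raise ValueError("estimates and variances must be equal-length, non-empty")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    m = q.size
    if m < 2:
        raise ValueError("Rubin's rules need m >= 2 imputations (B is undefined at m=1)")
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    b = float(np.sum((q - q_bar) ** 2) / (m - 1))
    t = u_bar + (1.0 + 1.0 / m) * b
    return PooledEstimate(q_bar=q_bar, u_bar=u_bar, b_between=b, t_total=t, m=m)


@dataclass(frozen=True)
class MIFit:
    """Pooled two-equation fit: per-coefficient Rubin combinations plus
    PiecewiseFit views (coef = q_bar, se = sqrt(T)) usable downstream for the
    indirect effect."""

    pooled_m: dict
    pooled_y: dict
    m_fit: PiecewiseFit
    y_fit: PiecewiseFit
    n_imputations: int
    n_failed: int


def _pooled_fit(method, equation, pooled: dict, template: PiecewiseFit, rhos):
    coef = {k: p.q_bar for k, p in pooled.items()}
    se = {k: p.se for k, p in pooled.items()}
    rho = float(np.mean(rhos)) if rhos else None
    return PiecewiseFit(
        method=method,
        equation=equation,
        coef=coef,
        se=se,
        residuals=template.residuals,
        n_used=template.n_used,
        rho_hat=rho,
        sigma2=template.sigma2,
        converged=True,
    )


def fit_with_mi(
    series: SCEDSeries,
    method: str = "OLS",
    m: int = DEFAULT_M,
    iterations: int = DEFAULT_ITERATIONS,
    seed=0,
    anchor: int = 0,
    engine: str = "pmm",
    donor_pool: int = DEFAULT_DONOR_POOL,
    imputations: ImputationSet | None = None,
) -> MIFit:
    """Impute, fit both piecewise equations per completed dataset, pool.

    A complete series short-circuits to a single fit (B = 0, T = U).  Each
    coefficient is pooled on the coefficient scale; the pooled a- and b-paths
    and their total-variance SEs are what the Monte-Carlo indirect-effect CI
    consumes.  Per-imputation fit failures are dropped with a warning; more
    than 20% failures aborts.  Pass ``imputations`` to reuse an existing
    :class:`ImputationSet` across methods.
    """
    if not series.has_missing():
        m_fit, y_fit = fit_equations(series, method, anchor=anchor)
        pooled_m = {
            k: PooledEstimate(m_fit.coef[k], m_fit.se[k] ** 2, 0.0, m_fit.se[k] ** 2, 1)
            for k in m_fit.coef
        }
        pooled_y = {
            k: PooledEstimate(y_fit.coef[k], y_fit.se[k] ** 2, 0.0, y_fit.se[k] ** 2, 1)
            for k in y_fit.coef
        }
        return MIFit(pooled_m, pooled_y, m_fit, y_fit, n_imputations=1, n_failed=0)

    imp = imputations if imputations is not None else impute_chained(
        series, m=m, iterations=iterations, seed=seed,
        donor_pool=donor_pool, engine=engine, anchor=anchor,
    )
    m_fits, y_fits = [], []
    failed = 0
    for ds in imp.datasets:
        try:
            mf, yf = fit_equations(ds, method, anchor=anchor)
            m_fits.append(mf)
            y_fits.append(yf)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            failed += 1
            warnings.warn(f"imputation fit failed and was dropped: {exc}", RuntimeWarning)
    if failed > MAX_FIT_FAILURE_FRACTION * imp.m or len(m_fits) < 2:
        raise EstimationError(
            f"{failed}/{imp.m} imputation fits failed; cannot pool reliably"
        )

    pooled_m = {
        k: pool_rubin([f.coef[k] for f in m_fits], [f.se[k] ** 2 for f in m_fits])
        for k in m_fits[0].coef
    }
    pooled_y = {
        k: pool_rubin([f.coef[k] for f in y_fits], [f.se[k] ** 2 for f in y_fits])
        for k in y_fits[0].coef
    }
    rhos_m = [f.rho_hat for f in m_fits if f.rho_hat is not None]
    rhos_y = [f.rho_hat for f in y_fits if f.rho_hat is not None]
    return MIFit(
        pooled_m,
        pooled_y,
        _pooled_fit(m_fits[0].method, "M", pooled_m, m_fits[0], rhos_m),
        _pooled_fit(y_fits[0].method, "Y", pooled_y, y_fits[0], rhos_y),
        n_imputations=len(m_fits),
        n_failed=failed,
    )
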