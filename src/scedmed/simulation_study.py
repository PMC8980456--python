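"""Monte-Carlo evaluation engine for the piecewise mediation model.

Generates AB single-case series with linear deterministic trends and
stationary AR(1) errors, analyzes each replication with the requested
estimators, and summarizes the behaviour of the indirect-effect point and
Monte-Carlo interval estimates: bias, relative bias, efficiency (SD of the
point estimate), rejection rate (power when the true indirect effect is
nonzero, type-I error when it is zero), coverage, and mean interval width.

The generator's conventions deserve note.  Innovations have unit variance
and the AR(1) process is started from its stationary distribution, so the
marginal error variance is 1/(1-rho^2) — error noise grows with rho, which
is what drives the loss of power at high autocorrelation.  The mediator and
outcome error processes are independent; the outcome inherits mediator noise
only through the b-path term.

Factorial grids are described by a small config mapping (YAML-loadable):
factor levels for n_total, a_level, a_trend, b_path, rho and missing_prop
are crossed into conditions; every condition is analyzed by all requested
methods on the same generated data, which removes between-method Monte-Carlo
noise from method comparisons.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import missing_data
from .estimators import METHODS, EstimationError, fit_equations
from .mediation_effects import (
    EFFECT_KINDS,
    ci_covers,
    ci_excludes_zero,
    indirect_effect,
)
from .missing_data import ampute_mcar, fit_with_mi, impute_chained
from .sced_data import SCEDSeries, build_design

__all__ = [
    "SimulationCondition",
    "PerformanceSummary",
    "generate_sced",
    "run_condition",
    "run_grid",
    "enumerate_conditions",
    "load_config",
]

logger = logging.getLogger("scedmed.simulation")

DEFAULT_CI_DRAWS = 10_000  # per-replication Monte-Carlo CI draws
MAX_FAILURE_FRACTION = 0.10

_NUISANCE_KEYS = ("b0M", "b1M", "b0Y", "b1Y", "b2Y", "b3Y")


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial design.

    ``a_level``/``a_trend`` are the mediator's change in level/trend at the
    phase switch, ``b_path`` the mediator-to-outcome slope, ``rho`` the error
    autocorrelation shared by both equations, ``missing_prop`` the MCAR
    occasion-level missingness proportion.  Nuisance coefficients (baseline
    levels/trends and the outcome's direct phase effects) default to zero;
    they do not move the true indirect effects.
    """

    n_total: int
    a_level: float = 0.0
    a_trend: float = 0.0
    b_path: float = 0.0
    rho: float = 0.0
    missing_prop: float = 0.0
    method: str = "all"
    nuisance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total % 2 != 0 or self.n_total < 8:
            raise ValueError("n_total must be even and >= 8 (equal AB phases)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 <= self.missing_prop < 1.0:
            raise ValueError("missing_prop must be in [0, 1)")
        unknown = set(self.nuisance) - set(_NUISANCE_KEYS)
        if unknown:
            raise ValueError(f"unknown nuisance coefficients: {sorted(unknown)}")

    def truth(self, kind: str) -> float:
        """Population indirect effect a*b for the given kind."""
        a = self.a_level if kind == "level" else self.a_trend
        return a * self.b_path

    def methods(self) -> tuple[str, ...]:
        return METHODS if self.method == "all" else (self.method.upper(),)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "a_level": self.a_level,
            "a_trend": self.a_trend,
            "b_path": self.b_path,
            "rho": self.rho,
            "missing_prop": self.missing_prop,
        }


@dataclass(frozen=True)
class PerformanceSummary:
    """Replication-level summary for one condition x method x effect kind.

    ``rejection_rate`` is power when ``truth`` is nonzero and the type-I
    error rate when it is zero; ``relative_bias`` is (mean - truth)/truth and
    None when the truth is zero.
    """

    condition: SimulationCondition
    method: str
    kind: str
    truth: float
    n_reps: int
    n_failed: int
    bias: float
    relative_bias: float | None
    sd_estimate: float
    rejection_rate: float
    coverage: float
    mean_width: float

    def to_row(self) -> dict:
        row = self.condition.to_dict()
        row.update(
            {
                "method": self.method,
                "kind": self.kind,
                "truth": self.truth,
                "n_reps": self.n_reps,
                "n_failed": self.n_failed,
                "bias": self.bias,
                "relative_bias": self.relative_bias,
                "sd_estimate": self.sd_estimate,
                "rejection_rate": self.rejection_rate,
                "coverage": self.coverage,
                "mean_width": self.mean_width,
            }
        )
        return row


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, t: int, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with unit-variance innovations (marginal
    variance 1/(1-rho^2))."""
    nu = rng.standard_normal(t)
    if rho == 0.0:
        return nu
    e = np.empty(t)
    e[0] = rho * rng.normal(0.0, 1.0 / np.sqrt(1.0 - rho * rho)) + nu[0]
    for i in range(1, t):
        e[i] = rho * e[i - 1] + nu[i]
    return e


def generate_sced(
    condition: SimulationCondition, seed=0, noise_scale: float = 1.0
) -> SCEDSeries:
    """Simulate one complete AB series with equal phase lengths.

    Mediator: b0M + b1M*time + a_level*phase + a_trend*phase_time + e_M;
    outcome adds the direct phase effects and b_path times the realized
    mediator.  e_M and e_Y are independent stationary AR(1) processes.
    ``noise_scale=0`` returns the deterministic trends exactly (debugging).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = condition.n_total
    phase = np.repeat([0, 1], t // 2)
    shell = SCEDSeries(phase, np.zeros(t), np.zeros(t))
    x = build_design(shell).x  # intercept, time, phase, phase_time
    nz = {k: float(condition.nuisance.get(k, 0.0)) for k in _NUISANCE_KEYS}

    e_m = _ar1_noise(rng, t, condition.rho) * noise_scale
    e_y = _ar1_noise(rng, t, condition.rho) * noise_scale
    m = x @ [nz["b0M"], nz["b1M"], condition.a_level, condition.a_trend] + e_m
    y = (
        x @ [nz["b0Y"], nz["b1Y"], nz["b2Y"], nz["b3Y"]]
        + condition.b_path * m
        + e_y
    )
    return SCEDSeries(phase, m, y)


# ---------------------------------------------------------------------------
# replication loop
# ---------------------------------------------------------------------------


def _replication_seed(base_seed: int, cond_index: int, rep: int) -> np.random.SeedSequence:
    """Deterministic per-replication seed stream."""
    return np.random.SeedSequence(base_seed, spawn_key=(cond_index, rep))


def run_condition(
    condition: SimulationCondition,
    n_reps: int = 1000,
    ci_draws: int = DEFAULT_CI_DRAWS,
    alpha: float = 0.05,
    base_seed: int = 0,
    cond_index: int = 0,
    mi_m: int = missing_data.DEFAULT_M,
    mi_iterations: int = missing_data.DEFAULT_ITERATIONS,
) -> dict[tuple[str, str], PerformanceSummary]:
    """Run one condition; returns summaries keyed (method, effect kind).

    Every replication generates one dataset and analyzes it with all of the
    condition's methods; with missingness the imputation set is also shared
    across methods.  Replications where a method's fit fails are excluded for
    that method (counted in ``n_failed``; a condition with more than 10%
    exclusions is flagged in the log).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = condition.methods()
    results: dict[tuple[str, str], dict[str, list]] = {
        (meth, kind): {"point": [], "low": [], "high": []}
        for meth in methods
        for kind in EFFECT_KINDS
    }
    failures = {meth: 0 for meth in methods}
    t0 = time.perf_counter()

    for rep in range(n_reps):
        ss = _replication_seed(base_seed, cond_index, rep)
        s_gen, s_amp, s_mi, s_ci = ss.spawn(4)
        series = generate_sced(condition, np.random.default_rng(s_gen))
        rng_ci = np.random.default_rng(s_ci)

        imputations = None
        if condition.missing_prop > 0.0:
            try:
                series = ampute_mcar(
                    series, condition.missing_prop, np.random.default_rng(s_amp)
                )
                imputations = impute_chained(
                    series, m=mi_m, iterations=mi_iterations, seed=s_mi
                )
            except EstimationError as exc:
                logger.debug("rep %d: amputation/imputation failed: %s", rep, exc)
                for meth in methods:
                    failures[meth] += 1
                continue

        for meth in methods:
            try:
                # per-fit convergence warnings are summarized in the log
                # instead of being raised once per replication
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if imputations is not None:
                        mi = fit_with_mi(series, meth, imputations=imputations)
                        m_fit, y_fit = mi.m_fit, mi.y_fit
                    else:
                        m_fit, y_fit = fit_equations(series, meth)
                for kind in EFFECT_KINDS:
                    est = indirect_effect(
                        m_fit, y_fit, kind, alpha=alpha, n_draws=ci_draws, seed=rng_ci
                    )
                    bucket = results[(meth, kind)]
                    bucket["point"].append(est.point)
                    bucket["low"].append(est.ci_low)
                    bucket["high"].append(est.ci_high)
            except (EstimationError, np.linalg.LinAlgError) as exc:
                failures[meth] += 1
                logger.debug("rep %d method %s failed: %s", rep, meth, exc)

    summaries = {}
    for meth in methods:
        if failures[meth] > MAX_FAILURE_FRACTION * n_reps:
            logger.warning(
                "condition %s method %s: %d/%d replications excluded",
                condition.to_dict(), meth, failures[meth], n_reps,
            )
        for kind in EFFECT_KINDS:
            bucket = results[(meth, kind)]
            points = np.asarray(bucket["point"])
            lows = np.asarray(bucket["low"])
            highs = np.asarray(bucket["high"])
            truth = condition.truth(kind)
            if points.size == 0:
                raise EstimationError(
                    f"all replications failed for method {meth} in {condition}"
                )
            bias = float(points.mean() - truth)
            rel = None if truth == 0.0 else float(bias / truth)
            excl = (lows > 0.0) | (highs < 0.0)
            cover = (lows <= truth) & (truth <= highs)
            summaries[(meth, kind)] = PerformanceSummary(
                condition=condition,
                method=meth,
                kind=kind,
                truth=truth,
                n_reps=int(points.size),
                n_failed=failures[meth],
                bias=bias,
                relative_bias=rel,
                sd_estimate=float(points.std(ddof=1)) if points.size > 1 else 0.0,
                rejection_rate=float(excl.mean()),
                coverage=float(cover.mean()),
                mean_width=float((highs - lows).mean()),
            )
    logger.info(
        "condition %s done in %.1fs (%d reps, failures %s)",
        condition.to_dict(), time.perf_counter() - t0, n_reps, failures,
    )
    return summaries


# ---------------------------------------------------------------------------
# factorial grids
# ---------------------------------------------------------------------------

_FACTOR_KEYS = ("n_total", "a_level", "a_trend", "b_path", "rho", "missing_prop")
_CONDITION_COLS = list(_FACTOR_KEYS) + ["method", "kind"]


def load_config(path) -> dict:
    """Load a YAML grid config."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("grid config must be a mapping")
    return cfg


def _levels(cfg: dict, key: str, default=None):
    v = cfg.get(key, default)
    if v is None:
        raise ValueError(f"grid config missing required key {key!r}")
    if not isinstance(v, (list, tuple)):
        v = [v]
    return list(v)


def enumerate_conditions(cfg: dict) -> list[SimulationCondition]:
    """Cross the factor levels of a grid config into conditions (methods are
    crossed later, within each condition's analysis)."""
    methods = [m.upper() for m in _levels(cfg, "methods", list(METHODS))]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r} in config")
    method = "all" if set(methods) == set(METHODS) else None
    nuisance = cfg.get("nuisance", {}) or {}
    conditions = []
    for n, a_l, a_t, b, rho, miss in itertools.product(
        _levels(cfg, "n_total"),
        _levels(cfg, "a_level"),
        _levels(cfg, "a_trend"),
        _levels(cfg, "b_path"),
        _levels(cfg, "rho"),
        _levels(cfg, "missing_prop", [0.0]),
    ):
        if method is not None:
            conditions.append(
                SimulationCondition(
                    int(n), float(a_l), float(a_t), float(b), float(rho),
                    float(miss), method="all", nuisance=nuisance,
                )
            )
        else:
            for meth in methods:
                conditions.append(
                    SimulationCondition(
                        int(n), float(a_l), float(a_t), float(b), float(rho),
                        float(miss), method=meth, nuisance=nuisance,
                    )
                )
    return conditions


def run_grid(
    cfg: dict,
    out_path=None,
    n_reps: int | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run the full factorial grid; tidy one-row-per-summary results.

    ``out_path`` (CSV) makes the run resumable: rows already present for a
    condition are kept and the condition skipped, and partial results are
    flushed after every condition so an interrupt preserves finished cells.
    """
    conditions = enumerate_conditions(cfg)
    reps = int(n_reps if n_reps is not None else cfg.get("n_reps", 1000))
    seed = int(base_seed if base_seed is not None else cfg.get("seed", 0))
    ci_draws = int(cfg.get("ci_draws", DEFAULT_CI_DRAWS))
    alpha = float(cfg.get("alpha", 0.05))
    mi_cfg = cfg.get("mi", {}) or {}
    mi_m = int(mi_cfg.get("m", missing_data.DEFAULT_M))
    mi_iterations = int(mi_cfg.get("iterations", missing_data.DEFAULT_ITERATIONS))

    done = pd.DataFrame()
    if out_path is not None:
        try:
            done = pd.read_csv(out_path, float_precision="round_trip")
        except (FileNotFoundError, pd.errors.EmptyDataError):
            done = pd.DataFrame()

    rows = [] if done.empty else done.to_dict("records")
    done_keys = set()
    if not done.empty:
        done_keys = {
            tuple(r[k] for k in _FACTOR_KEYS) for r in rows
        }

    ran_any = False
    for idx, cond in enumerate(conditions):
        key = tuple(float(v) if k != "n_total" else int(v)
                    for k, v in cond.to_dict().items())
        if key in done_keys:
            logger.info("skipping already-computed condition %s", cond.to_dict())
            continue
        ran_any = True
        summaries = run_condition(
            cond, n_reps=reps, ci_draws=ci_draws, alpha=alpha,
            base_seed=seed, cond_index=idx, mi_m=mi_m, mi_iterations=mi_iterations,
        )
        for summary in summaries.values():
            rows.append(summary.to_row())
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, index=False)
    table = pd.DataFrame(rows)
    if out_path is not None and ran_any:
        table.to_csv(out_path, index=False)
    return table
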