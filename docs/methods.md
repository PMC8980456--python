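# Methods

## Design coding

An AB series is coded with four predictors: intercept, `time` (0-based
occasion index), `phase` (0/1), and `phase_time = phase · (time − t_B +
anchor)` where `t_B` is the first intervention occasion. With the default
`anchor = 0` the intercept is the expected level at the very first baseline
occasion, the phase coefficient is the immediate change in level at
intervention onset, and the phase_time coefficient is the change in slope
between phases. Published analyses differ on whether the within-phase-B
clock starts at 0 or 1; the anchor is therefore exposed (`--phase-time-anchor`
in the CLI, `anchor=` in the library). The choice shifts only the
interpretation of the level-change coefficient by one slope step; the trend
coefficients are unaffected. The design matrix has full column rank for
every AB split with at least two occasions per phase (verified exhaustively
for T ≤ 40 in the tests).

## Estimators

All four routes fit the same two piecewise equations; they differ in how
serial correlation enters.

* **OLS** — classical SEs `σ̂²(XᵀX)⁻¹` with denominator n − p.
* **NW** — OLS coefficients (identical by construction) with a Bartlett-kernel
  HAC covariance: weights `w_ℓ = 1 − ℓ/(L+1)` over lags 0..L, automatic lag
  `L = ⌊4(n/100)^{2/9}⌋`, no small-sample correction. At L = 0 this reduces
  to the White (HC0) covariance. Different HAC kernels/bandwidths in other
  software will give somewhat different SEs; the lag rule is a parameter.
* **FGLS** — iterative Cochrane-Orcutt: OLS, lag-1 residual autocorrelation
  `ρ̂ = Σ e_t e_{t−1} / Σ e_t²` (clipped to |ρ̂| ≤ 0.999), quasi-differencing
  `z*_t = z_t − ρ̂ z_{t−1}` of the response *and every design column* with
  the first observation dropped, OLS on the starred data, repeat until
  |Δρ̂| < 10⁻⁶ (max 100 iterations; non-convergence — typically a tiny
  oscillation in ρ̂ at high autocorrelation — returns the last iterate
  flagged `converged=False`). Because the intercept column is transformed
  along with the rest, coefficients come back directly on the original
  scale, and the starred regression's covariance supplies the SEs — this is
  algebraically the same as regressing on a raw intercept and rescaling the
  intercept and its SE by 1/(1−ρ̂).
* **AR1** — exact Gaussian ML of regression with stationary AR(1) errors.
  The likelihood uses the stationary initialization (first-error variance
  σ²_ν/(1−ρ²)); Prais-Winsten whitening makes β and σ²_ν available in
  closed form at fixed ρ, leaving a one-dimensional profile likelihood that
  is scanned on a 41-point grid over (−0.98, 0.98) and polished by bounded
  Brent search (the grid makes multi-start unnecessary). SEs are from the
  inverse observed information — a numerical Hessian of the exact
  log-likelihood over (β, ρ, σ²_ν) at the optimum — with the GLS
  conditional covariance as fallback if that Hessian is singular. The
  log-likelihood equals the dense multivariate-normal density with Toeplitz
  covariance `σ²_ν ρ^{|i−j|}/(1−ρ²)` (tested to 10⁻⁸) and matches the
  Kalman-filter exact likelihood of statsmodels' SARIMAX.

Estimation refuses series with fewer than three observed occasions per
phase, missing cells (resolve via MI first), or a rank-deficient design.

## Indirect effects and Monte-Carlo intervals

The a-path is the mediator's change in level (b2M) or trend (b3M); the
b-path is the mediator coefficient in the outcome equation (b4Y). The CI
for the product draws `a*` and `b*` independently (the two equations are
estimated separately; their sampling covariance is ignored — the standard
assumption for this interval), forms `a*·b*`, and takes empirical
α/2 and 1−α/2 quantiles with linear order-statistic interpolation. Default
100,000 draws for user-facing analyses; 10,000 inside simulation loops
(quantile noise at 10⁴ draws is well below replication noise). With both
SEs zero the interval degenerates to the point. The 97.5% quantile of the
null case (a = b = 0, unit SEs) is ±2.18, reproduced in tests against a
large-sample oracle.

## Missing data

The amputation routine models occasion-level MCAR: exactly `round(prop·T)`
occasions are drawn uniformly and the mediator and outcome are blanked
jointly there, mirroring a participant skipping a diary entry; the design
variables stay known. Amputations leaving fewer than three jointly-observed
occasions in a phase are refused.

Imputation is by chained equations: the mediator model regresses on (time,
phase, phase_time, outcome) and the outcome model on (time, phase,
phase_time, mediator); each chain initializes holes from random observed
values and runs five sweeps (default). The univariate engine is
predictive-mean matching with a donor pool of 5 — Bayesian parameter draws
(scaled-inverse-χ² variance, normal coefficients) rank the missing cells'
predicted means against the observed cells' fitted means, and each hole
receives the observed value of a randomly chosen near donor, so imputations
never leave the observed range. A normal-linear engine is available
(`engine="norm"`). Defaults are m = 100 imputations × 5 iterations,
following the convention that the number of imputations should be at least
the missingness percentage; both are configurable and the simulation tests
use smaller m for speed. A degenerate predictor matrix inside a sweep falls
back to an unconditional mean-plus-noise draw, with a warning.

Pooling follows Rubin's rules per coefficient: `Q̄ = mean(Q̂_j)`,
`Ū = mean(Û_j)`, `B = var(Q̂_j)`, `T = Ū + (1 + 1/m)B`, SE = √T. Pooling is
on the coefficient scale — the pooled a and b (with √T SEs) feed the same
Monte-Carlo interval as complete-data fits — not on the product scale.
The chained-equation engine is implemented in-package so that every draw
runs off an explicit `numpy` Generator: the simulation engine's
reproducibility contract (bitwise-identical results given a base seed)
requires per-replication seed streams that global-state imputation code
cannot provide.

## Simulation engine

The generator emulates the study conditions: equal A and B phase lengths;
deterministic linear trends per equation with all nuisance coefficients
(baseline levels/trends, direct phase effects on the outcome) defaulting
to 0; errors iid N(0, 1) at ρ = 0 and otherwise stationary AR(1) with
unit-variance innovations and a stationary start, so the marginal error
variance is 1/(1−ρ²) — at ρ = 0.9 the error SD is ≈ 2.3, which is what
drives the loss of power and efficiency at high autocorrelation. The
mediator and outcome error processes are independent; outcome noise picks
up mediator noise only through the b-path. Factor levels mirror the study:
N ∈ {20, 30, 60, 100}, a_level ∈ {0, 2}, a_trend ∈ {0, 0.2},
b ∈ {0, 0.59}, ρ ∈ {0, 0.1, 0.5, 0.9}, missingness ∈ {0, 0.2, 0.5} — 128
complete-data and 256 missing-data parameter combinations.

Every replication's data are analyzed by all requested methods (and one
imputation set is shared across methods), so method contrasts are paired
and free of between-method generation noise. Per-replication seeds derive
from `SeedSequence(base_seed, spawn_key=(condition_index, replication))`,
giving reproducible, order-independent streams. Metrics per condition ×
method × effect kind: bias, relative bias `(mean − truth)/truth` (reported
with this sign convention; some sources print the negated ratio — the
magnitude is what the ±0.10 acceptability band concerns — and it is
undefined at truth 0), SD of the point estimate, rejection rate (power or
type-I error), coverage of the truth `a·b`, and mean interval width.
Replications where a method fails (e.g. an amputation refusal at small N)
are excluded for that method and counted; conditions with > 10% exclusions
are flagged in the log.

Grid runs stream results to a tidy CSV after every condition and are
resumable: conditions already present in the output file are skipped.

## Problem sizes

The headline checks run 1000 replications per condition with 10⁴ CI draws
per replication — the full acceptance recomputation is about one minute on
one CPU, and the complete test suite under two minutes. Parameter-recovery
tests use n = 5000 series; distributional oracles use 10⁶–10⁷ draws.

## Known limitations

* AB designs with equally spaced occasions only; no multiple-baseline,
  ABAB, or alternating-treatment designs.
* AR(1) errors only (no higher-order AR, MA, or integrated processes); the
  condition grid covers ρ ∈ [0, 1) — negative autocorrelation is supported
  by the estimators but not studied.
* MCAR missingness only; MAR/MNAR mechanisms and time-series-specific
  imputation engines are out of scope.
* The Monte-Carlo interval ignores the sampling covariance between the two
  equations' coefficient estimates.
* The generator's linear-trend, Gaussian, homoskedastic world is idealized;
  passing simulations demonstrate estimator behaviour under that model, not
  robustness to non-linearity, outliers, or heavy tails in real diaries.
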