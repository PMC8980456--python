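"""Indirect effects and Monte-Carlo confidence intervals.

In the piecewise mediation model two indirect effects of the phase change on
the outcome are of interest, each a product of coefficients:

* ``level``: (change in mediator level at intervention onset) x (mediator
  slope in the outcome equation), i.e. b2 of the M-equation times b4 of the
  Y-equation;
* ``trend``: (change in mediator trend) x (mediator slope), b3 x b4.

The sampling distribution of a product of two estimates is skewed, so the
interval comes from the Monte-Carlo method: draw the two coefficients
independently from normal distributions centred at their estimates with their
standard errors, and take empirical quantiles of the products.  The a-draw
comes from the M-equation fit and the b-draw from the Y-equation fit; their
sampling covariance is ignored (the two equations are estimated separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import PiecewiseFit

__all__ = [
    "IndirectEffectEstimate",
    "EFFECT_KINDS",
    "monte_carlo_ci",
    "indirect_effect",
    "ci_excludes_zero",
    "ci_covers",
]

EFFECT_KINDS = ("level", "trend")
_A_COEF = {"level": "b2", "trend": "b3"}

DEFAULT_DRAWS = 100_000


@dataclass(frozen=True)
class IndirectEffectEstimate:
    """Point and Monte-Carlo interval estimate of one indirect effect.

    ``point = a_hat * b_hat``; ``se_product`` is the first-order delta-method
    SE ``sqrt(a^2 se_b^2 + b^2 se_a^2)`` (reported for reference, not used in
    the interval).  The interval is generally asymmetric around the point.
    """

    kind: str
    method: str
    a_hat: float
    se_a: float
    b_hat: float
    se_b: float
    point: float
    ci_low: float
    ci_high: float
    alpha: float
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"kind must be one of {EFFECT_KINDS}")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def se_product(self) -> float:
        return float(
            np.sqrt(self.a_hat**2 * self.se_b**2 + self.b_hat**2 * self.se_a**2)
        )

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "method": self.method,
            "a_hat": self.a_hat,
            "se_a": self.se_a,
            "b_hat": self.b_hat,
            "se_b": self.se_b,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se_product": self.se_product,
            "alpha": self.alpha,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def monte_carlo_ci(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    alpha: float = 0.05,
    n_draws: int = DEFAULT_DRAWS,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[float, float]:
    """Empirical (alpha/2, 1-alpha/2) quantiles of products of independent
    normal draws a* ~ N(a, se_a^2), b* ~ N(b, se_b^2).

    Quantiles use linear interpolation of order statistics; with both SEs zero
    the interval degenerates to the point a*b.  Reproducible given ``seed``
    (an int, SeedSequence, or an already-constructed Generator).
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable quantiles")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prod = rng.normal(a, se_a, n_draws) * rng.normal(b, se_b, n_draws)
    low, high = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def indirect_effect(
    m_fit: PiecewiseFit,
    y_fit: PiecewiseFit,
    kind: str = "level",
    alpha: float = 0.05,
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> IndirectEffectEstimate:
    """Indirect effect of phase on outcome through the mediator.

    ``kind='level'`` takes the a-path from the mediator's change in level
    (b2 of the M-equation), ``kind='trend'`` from its change in trend (b3);
    the b-path is always the mediator coefficient b4 of the Y-equation.  Both
    fits must come from the same estimation method.
    """
    if kind not in EFFECT_KINDS:
        raise ValueError(f"kind must be one of {EFFECT_KINDS}")
    if m_fit.equation != "M" or y_fit.equation != "Y":
        raise ValueError("pass the M-equation fit first and the Y-equation fit second")
    if m_fit.method != y_fit.method:
        raise ValueError(
            f"fits use different methods ({m_fit.method} vs {y_fit.method})"
        )
    a_name = _A_COEF[kind]
    a_hat, se_a = m_fit.coef[a_name], m_fit.se[a_name]
    b_hat, se_b = y_fit.coef["b4"], y_fit.se["b4"]
    low, high = monte_carlo_ci(a_hat, se_a, b_hat, se_b, alpha, n_draws, seed)
    return IndirectEffectEstimate(
        kind=kind,
        method=m_fit.method,
        a_hat=float(a_hat),
        se_a=float(se_a),
        b_hat=float(b_hat),
        se_b=float(se_b),
        point=float(a_hat * b_hat),
        ci_low=low,
        ci_high=high,
        alpha=alpha,
        n_draws=n_draws,
        seed=int(seed) if np.isscalar(seed) else -1,
    )


def ci_excludes_zero(est: IndirectEffectEstimate) -> bool:
    """True when the interval lies entirely on one side of zero (the
    significance decision for the indirect effect)."""
    return est.ci_low > 0.0 or est.ci_high < 0.0


def ci_covers(est: IndirectEffectEstimate, truth: float) -> bool:
    """True when the closed interval contains ``truth``."""
    return est.ci_low <= truth <= est.ci_high
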