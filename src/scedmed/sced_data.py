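"""Data model for AB-design single-case series and piecewise-regression coding.

A single-case experimental design (SCED) observes one participant repeatedly
across a baseline phase (A) and an intervention phase (B).  Each measurement
occasion carries a mediator value ``m`` and an outcome value ``y``, either of
which may be missing.  This module holds the series container, the predictor
coding used by the piecewise (interrupted time-series) regression, and CSV
round-trip I/O.

Predictor coding
----------------
The design matrix has four columns: an intercept, ``time`` (the 0-based
occasion index, so the intercept is the expected level at the very first
baseline occasion), ``phase`` (0 in A, 1 in B), and ``phase_time`` — the
within-B recentred time, ``phase * (time - t_B + anchor)`` with ``t_B`` the
first B occasion.  With the default ``anchor=0`` the phase coefficient is the
immediate change in level at the onset of the intervention, and the
phase_time coefficient is the change in slope between the phases.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SCEDSeries",
    "DesignMatrix",
    "SCEDError",
    "ParseError",
    "StructureError",
    "DegenerateDesignError",
    "build_design",
    "read_sced_csv",
    "write_sced_csv",
]

DESIGN_COLUMNS = ("intercept", "time", "phase", "phase_time")


class SCEDError(ValueError):
    """Base class for SCED input problems."""


class ParseError(SCEDError):
    """Malformed SCED CSV."""


class StructureError(SCEDError):
    """Phase pattern is not a single A-to-B changepoint."""


class DegenerateDesignError(SCEDError):
    """Too few occasions in a phase for the piecewise design to be identified."""


@dataclass(frozen=True)
class SCEDSeries:
    """One participant's AB series: phase indicator, mediator, outcome.

    Occasions are the consecutive integers ``0..T-1``; missing mediator or
    outcome values are stored as NaN.
    """

    phase: np.ndarray
    m: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=int)
        m = np.asarray(self.m, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (phase.shape == m.shape == y.shape) or phase.ndim != 1:
            raise SCEDError("phase, m, y must be 1-d arrays of equal length")
        if phase.size and not np.isin(phase, (0, 1)).all():
            raise StructureError("phase must be coded 0 (A) or 1 (B)")
        if np.any(np.diff(phase) < 0):
            raise StructureError(
                "phase must be non-decreasing (single A->B changepoint)"
            )
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "y", y)

    @property
    def n_occasions(self) -> int:
        return self.phase.size

    @property
    def occasion(self) -> np.ndarray:
        return np.arange(self.n_occasions)

    @property
    def t_b(self) -> int:
        """Index of the first phase-B occasion (== length of phase A)."""
        idx = np.flatnonzero(self.phase == 1)
        if idx.size == 0:
            raise StructureError("series has no phase-B occasions")
        return int(idx[0])

    def phase_lengths(self) -> tuple[int, int]:
        n_b = int(self.phase.sum())
        return self.n_occasions - n_b, n_b

    def n_observed(self, var: str = "both") -> np.ndarray:
        """Observed-occasion counts per phase for 'm', 'y' or 'both'."""
        if var == "m":
            ok = ~np.isnan(self.m)
        elif var == "y":
            ok = ~np.isnan(self.y)
        else:
            ok = ~np.isnan(self.m) & ~np.isnan(self.y)
        return np.array([ok[self.phase == 0].sum(), ok[self.phase == 1].sum()])

    def has_missing(self) -> bool:
        return bool(np.isnan(self.m).any() or np.isnan(self.y).any())

    def copy(self) -> "SCEDSeries":
        return SCEDSeries(self.phase.copy(), self.m.copy(), self.y.copy())


@dataclass(frozen=True)
class DesignMatrix:
    """Piecewise-regression predictors aligned to the occasions of a series."""

    x: np.ndarray  # (T, 4) columns: intercept, time, phase, phase_time
    anchor: int = 0
    columns: tuple[str, ...] = field(default=DESIGN_COLUMNS)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.x[:, self.columns.index(name)]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.x))


def build_design(series: SCEDSeries, anchor: int = 0) -> DesignMatrix:
    """Predictor coding for the piecewise regression of an AB series.

    ``anchor`` shifts where within-B time restarts: 0 (default) makes
    phase_time zero at the first B occasion, so the phase coefficient is the
    level change at intervention onset; 1 reproduces codings that start the
    B-phase clock at one.  Deterministic and independent of m/y values.
    """
    n_a, n_b = series.phase_lengths()
    if n_a < 2 or n_b < 2:
        raise DegenerateDesignError(
            f"need >= 2 occasions per phase, got A={n_a}, B={n_b}"
        )
    time = series.occasion.astype(float)
    phase = series.phase.astype(float)
    phase_time = phase * (time - series.t_b + anchor)
    x = np.column_stack([np.ones_like(time), time, phase, phase_time])
    return DesignMatrix(x=x, anchor=anchor)


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: comma-separated UTF-8, header `occasion,phase,m,y`,
# "." decimal, empty cell = missing, phase written as A/B (A/B or 0/1 read).
# ---------------------------------------------------------------------------

_PHASE_MAP = {"A": 0, "B": 1, "0": 0, "1": 1}


def read_sced_csv(path) -> SCEDSeries:
    """Read one participant's series; raises :class:`ParseError` with the
    offending row on malformed input."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["occasion", "phase", "m", "y"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing required column(s): {', '.join(missing_cols)}")

    occasions, phases, ms, ys = [], [], [], []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2  # 1-based, after header
        try:
            occ = int(row.occasion)
        except ValueError as exc:
            raise ParseError(f"row {rowno}: bad occasion {row.occasion!r}") from exc
        if occ in seen:
            raise ParseError(f"row {rowno}: duplicated occasion {occ}")
        seen.add(occ)
        ph = _PHASE_MAP.get(str(row.phase).strip().upper())
        if ph is None:
            raise ParseError(f"row {rowno}: phase must be A/B or 0/1, got {row.phase!r}")
        try:
            m = float(row.m) if str(row.m).strip() != "" else np.nan
            y = float(row.y) if str(row.y).strip() != "" else np.nan
        except ValueError as exc:
            raise ParseError(f"row {rowno}: non-numeric m/y value") from exc
        occasions.append(occ)
        phases.append(ph)
        ms.append(m)
        ys.append(y)

    order = np.argsort(occasions)
    occ_sorted = np.asarray(occasions)[order]
    if occ_sorted.size and not np.array_equal(occ_sorted, np.arange(occ_sorted.size)):
        raise ParseError("occasions must be the consecutive integers 0..T-1")
    phases_arr = np.asarray(phases)[order]
    if np.any(np.diff(phases_arr) < 0):
        bad = int(np.flatnonzero(np.diff(phases_arr) < 0)[0]) + 1
        raise ParseError(f"row {bad + 2}: phase reverts from B to A (non-AB pattern)")
    return SCEDSeries(
        phase=phases_arr,
        m=np.asarray(ms, dtype=float)[order],
        y=np.asarray(ys, dtype=float)[order],
    )


def _fmt(v: float) -> str:
    if np.isnan(v):
        return ""
    return repr(float(v))


def write_sced_csv(series: SCEDSeries, path) -> None:
    """Write the canonical CSV form (phase as A/B, empty cell = missing)."""
    buf = io.StringIO()
    buf.write("occasion,phase,m,y\n")
    for t in range(series.n_occasions):
        ph = "B" if series.phase[t] == 1 else "A"
        buf.write(f"{t},{ph},{_fmt(series.m[t])},{_fmt(series.y[t])}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
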