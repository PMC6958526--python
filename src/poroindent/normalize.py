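"""Normalization of ramp-and-hold force-time curves and collapse testing.

Three schemes are supported:

``relaxation_fraction``
    y = [F(t) - F_inf] / [F_M - F_inf]; dimensionless, 1 at hold start and
    decaying to 0 at full drainage.
``hertz_scaled``
    y = F / (R^0.5 * delta_M^1.5); carries units N m^-2 and removes the
    Hertzian geometry prefactor, so curves from different indenter sizes
    and depths become comparable.
``time_over_RdeltaM``
    x = t / (R * delta_M); the time axis scaled by the squared contact
    radius (units s m^-2).  Folding in the diffusivity D would make it the
    fully dimensionless tau.

Curves of one material collapse under these normalizations only when their
effective approach velocity (and contact scale R*delta_M) match, which is
what :func:`collapse_metric` quantifies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import DomainError, RelaxationCurve

__all__ = [
    "NormalizationScheme",
    "NormalizedCurve",
    "estimate_F_inf",
    "segment_ramp_hold",
    "normalize_relaxation",
    "normalize_hertz_scaled",
    "normalize_time",
    "shift_hold_origin",
    "collapse_metric",
]


class NormalizationScheme(str, enum.Enum):
    RELAXATION_FRACTION = "relaxation_fraction"
    HERTZ_SCALED = "hertz_scaled"
    TIME_OVER_RDELTAM = "time_over_RdeltaM"


class DegenerateRelaxationError(DomainError):
    """The hold phase carries no poroelastic signal (F_M <= F_inf)."""


@dataclass
class NormalizedCurve:
    """A normalized (x, y) curve with its scheme and provenance recorded."""

    x: np.ndarray
    y: np.ndarray
    scheme: NormalizationScheme
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise DomainError("x and y must be 1-D arrays of equal length")
        if self.x.size >= 2 and np.any(np.diff(self.x) < 0):
            raise DomainError("normalized time axis must be non-decreasing")


def _hold_mask(curve: RelaxationCurve) -> np.ndarray:
    t_R = curve.t_R if curve.t_R is not None else float(curve.t[0])
    return curve.t >= t_R


def estimate_F_inf(curve: RelaxationCurve, tail_fraction: float = 0.05,
                   slope_threshold: float = 0.01) -> tuple[float, bool]:
    """Estimate the fully relaxed force F_inf from the hold-phase tail.

    Returns ``(F_inf, converged)``.  F_inf is the mean force over the final
    ``tail_fraction`` of the hold-phase duration (at least 2 samples).  The
    curve is judged converged when the relative tail slope
    ``|dF/dt| * t_end / F`` is below ``slope_threshold``; an unconverged
    estimate is still returned, flagged False.
    """
    hold = _hold_mask(curve)
    t = curve.t[hold]
    F = curve.F[hold]
    if t.size < 10:
        raise DomainError("hold phase must contain at least 10 samples")
    t0, t1 = t[0], t[-1]
    window_start = t1 - tail_fraction * (t1 - t0)
    tail = t >= window_start
    if tail.sum() < 2:
        tail = np.zeros_like(t, dtype=bool)
        tail[-2:] = True
    f_inf = float(np.mean(F[tail]))
    # robust tail slope via least squares on the window
    slope = float(np.polyfit(t[tail], F[tail], 1)[0])
    scale = abs(f_inf) if f_inf != 0 else np.abs(F).max()
    rel_slope = abs(slope) * t1 / scale if scale > 0 else np.inf
    return f_inf, bool(rel_slope <= slope_threshold)


def segment_ramp_hold(curve: RelaxationCurve) -> tuple[float, float, float]:
    """Locate the end of the ramp and return ``(t_R, F_M, delta_M)``.

    Metadata ``t_R`` takes precedence; otherwise the ramp end is the first
    time the depth channel reaches (1 - 1e-3) of its maximum.  F_M is the
    force at the end of the ramp (not the global maximum, which can be an
    inertial overshoot spike).
    """
    if curve.t_R is not None:
        t_R = float(curve.t_R)
    elif curve.delta is not None:
        dmax = float(curve.delta.max())
        idx = int(np.argmax(curve.delta >= (1.0 - 1e-3) * dmax))
        t_R = float(curve.t[idx])
    else:
        raise DomainError("cannot segment: no depth channel and no t_R metadata")
    i = int(np.searchsorted(curve.t, t_R))
    i = min(max(i, 0), len(curve) - 1)
    F_M = float(np.interp(t_R, curve.t, curve.F))
    if curve.delta_M is not None:
        delta_M = float(curve.delta_M)
    elif curve.delta is not None:
        delta_M = float(curve.delta.max())
    else:
        raise DomainError("cannot determine delta_M: no depth channel or metadata")
    return t_R, F_M, delta_M


def normalize_relaxation(curve: RelaxationCurve, F_inf: Optional[float] = None,
                         hold_only: bool = True) -> NormalizedCurve:
    """Relaxation-fraction normalization y = [F - F_inf] / [F_M - F_inf]."""
    if F_inf is None:
        if curve.F_inf is None:
            F_inf, _ = estimate_F_inf(curve)
        else:
            F_inf = float(curve.F_inf)
    if curve.F_M is not None:
        F_M = float(curve.F_M)
    else:
        _, F_M, _ = segment_ramp_hold(curve)
    if F_M <= F_inf:
        raise DegenerateRelaxationError(
            f"F_M = {F_M!r} <= F_inf = {F_inf!r}: no poroelastic relaxation signal"
        )
    src = curve if not hold_only else shift_hold_origin(curve)
    y = (src.F - F_inf) / (F_M - F_inf)
    return NormalizedCurve(
        src.t, y, NormalizationScheme.RELAXATION_FRACTION,
        source_id=curve.label,
        meta={"F_M": F_M, "F_inf": F_inf},
    )


def _require_geometry(curve: RelaxationCurve) -> tuple[float, float]:
    if curve.geometry is None or curve.delta_M is None:
        raise DomainError("R and delta_M metadata are required for this normalization")
    return curve.geometry.R, float(curve.delta_M)


def normalize_time(curve: RelaxationCurve) -> np.ndarray:
    """Scaled time x = t / (R * delta_M), units s m^-2 (D not folded in)."""
    R, delta_M = _require_geometry(curve)
    return curve.t / (R * delta_M)


def normalize_hertz_scaled(curve: RelaxationCurve,
                           hold_only: bool = False) -> NormalizedCurve:
    """Hertz-scaled normalization y = F / (R^0.5 * delta_M^1.5), x = t/(R*delta_M)."""
    R, delta_M = _require_geometry(curve)
    src = shift_hold_origin(curve) if hold_only else curve
    y = src.F / (np.sqrt(R) * delta_M ** 1.5)
    x = src.t / (R * delta_M)
    return NormalizedCurve(
        x, y, NormalizationScheme.HERTZ_SCALED, source_id=curve.label,
        meta={"R": R, "delta_M": delta_M},
    )


def shift_hold_origin(curve: RelaxationCurve) -> RelaxationCurve:
    """Return the hold-phase subset with its clock restarted at zero."""
    if curve.t_R is None:
        raise DomainError("t_R metadata required to shift the hold origin")
    mask = curve.t >= curve.t_R
    return RelaxationCurve(
        t=curve.t[mask] - curve.t_R,
        F=curve.F[mask],
        delta=None if curve.delta is None else curve.delta[mask],
        geometry=curve.geometry,
        t_R=0.0,
        F_M=curve.F_M,
        F_inf=curve.F_inf,
        delta_M=curve.delta_M,
        label=curve.label,
    )


def collapse_metric(curves: Sequence[NormalizedCurve], n_grid: int = 200) -> float:
    """Worst-case vertical spread between normalized curves.

    All curves are interpolated (piecewise-linear in log-x, because
    relaxation spans decades) onto a common log-spaced grid over the shared
    x-range; the metric is the maximum over the grid of (max - min) across
    curves.  0 means perfect collapse; the metric is permutation-invariant
    and unchanged by duplicating a curve.
    """
    if len(curves) < 2:
        raise DomainError("collapse_metric needs at least two curves")
    los, his = [], []
    for c in curves:
        x = c.x[c.x > 0]
        if x.size < 2:
            raise DomainError("each curve needs >= 2 samples at positive x")
        los.append(x.min())
        his.append(x.max())
    lo, hi = max(los), min(his)
    if lo >= hi:
        raise DomainError("curves have disjoint x-ranges")
    grid = np.geomspace(lo, hi, n_grid)
    ys = np.empty((len(curves), n_grid))
    for i, c in enumerate(curves):
        pos = c.x > 0
        ys[i] = np.interp(np.log(grid), np.log(c.x[pos]), c.y[pos])
    return float(np.max(ys.max(axis=0) - ys.min(axis=0)))
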