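"""Relaxation-phase-only diffusivity estimation (the step-indentation baseline).

The classical route to the poroelastic diffusivity fits the normalized hold
phase, [F(t) - F_inf]/[F_M - F_inf], to a step-response master function
g(tau) of tau = D t / a^2 with a = sqrt(R delta_M) the contact radius.
That construction assumes an instantaneous ramp; with a finite rise time
the early relaxation is smeared by fluid transport during loading and the
fitted D is biased low, increasingly so as t_R grows.  This module
implements the baseline so the finite-rise-time master-curve fit can be
compared against it on the same data.

The default kernel

    g(tau) = 0.491 exp(-0.908 sqrt(tau)) + 0.509 exp(-1.679 tau)

is the widely used spherical-indentation relaxation function from the
step-loading literature; it is external to this package's own model,
satisfies g(0) = 1, is monotone decreasing, and is fully pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .core import DomainError, RelaxationCurve, contact_radius
from .normalize import estimate_F_inf, normalize_relaxation

__all__ = [
    "RelaxationKernel",
    "HU_SPHERICAL_KERNEL",
    "RelaxationDiffusivityFit",
    "fit_D_relaxation",
    "compare_frameworks",
]


@dataclass(frozen=True)
class RelaxationKernel:
    """A step-response relaxation function g(tau): g(0)=1, monotone to 0."""

    g: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    def __post_init__(self) -> None:
        g0 = float(self.g(np.asarray(0.0)))
        if abs(g0 - 1.0) > 1e-6:
            raise DomainError(f"kernel must satisfy g(0) = 1, got {g0}")
        grid = np.geomspace(1e-6, 1e3, 64)
        vals = np.asarray(self.g(grid), dtype=float)
        if np.any(np.diff(vals) > 1e-12):
            raise DomainError("kernel must be non-increasing")


def _hu_spherical(tau):
    tau = np.asarray(tau, dtype=float)
    return 0.491 * np.exp(-0.908 * np.sqrt(tau)) + 0.509 * np.exp(-1.679 * tau)


#: Spherical step-indentation relaxation function (external literature).
HU_SPHERICAL_KERNEL = RelaxationKernel(g=_hu_spherical, name="hu_spherical")


class RelaxationDiffusivityFit(BaseEstimator):
    """Fit D from a single hold-phase relaxation curve.

    Minimizes sum_i [y_i - g(D t_i / a^2)]^2 over D on a log grid followed
    by bounded scalar refinement, with y the relaxation-fraction
    normalized hold force and t the hold-phase clock.

    Parameters
    ----------
    kernel : RelaxationKernel
        Step-response master function; default the spherical kernel above.
    D_bounds : tuple
        Search interval, default (1e-13, 1e-5) m^2/s.
    n_grid : int
        Log-grid resolution for the global search stage.

    Attributes
    ----------
    D_ : float
        Fitted diffusivity, m^2/s.
    sse_ : float
        Residual sum of squares at the optimum.
    flags_ : list of str
        ``f_inf_unconverged`` when the hold tail was still relaxing;
        ``boundary_estimate`` when D_ sits at a search bound (degenerate
        data, e.g. pure noise).
    """

    def __init__(self, kernel: RelaxationKernel = HU_SPHERICAL_KERNEL,
                 D_bounds: tuple = (1e-13, 1e-5), n_grid: int = 121):
        self.kernel = kernel
        self.D_bounds = D_bounds
        self.n_grid = n_grid

    def fit(self, X: RelaxationCurve, y=None):
        curve = X
        if curve.geometry is None or curve.delta_M is None:
            raise DomainError("curve needs geometry and delta_M metadata")
        a = float(contact_radius(curve.geometry.R, curve.delta_M))
        flags = []
        if curve.F_inf is None:
            f_inf, converged = estimate_F_inf(curve)
            if not converged:
                flags.append("f_inf_unconverged")
        else:
            f_inf = float(curve.F_inf)
        norm = normalize_relaxation(curve, F_inf=f_inf, hold_only=True)
        mask = norm.x > 0
        t, yv = norm.x[mask], norm.y[mask]
        if t.size < 5:
            raise DomainError("hold phase too short to fit")

        def sse(logD):
            return float(np.sum((yv - self.kernel.g(np.exp(logD) * t / a ** 2)) ** 2))

        lo, hi = np.log(self.D_bounds[0]), np.log(self.D_bounds[1])
        grid = np.linspace(lo, hi, self.n_grid)
        vals = np.array([sse(x) for x in grid])
        i = int(np.argmin(vals))
        glo, ghi = grid[max(i - 1, 0)], grid[min(i + 1, self.n_grid - 1)]
        res = optimize.minimize_scalar(sse, bounds=(glo, ghi), method="bounded",
                                       options={"xatol": 1e-12})
        logD = float(res.x)
        if i in (0, self.n_grid - 1):
            flags.append("boundary_estimate")
        self.D_ = float(np.exp(logD))
        self.sse_ = float(res.fun)
        self.flags_ = flags
        self.contact_radius_ = a
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Normalized relaxation fraction at hold times t (s)."""
        if not hasattr(self, "D_"):
            raise DomainError("estimator is not fitted")
        t = np.asarray(t, dtype=float)
        return self.kernel.g(self.D_ * t / self.contact_radius_ ** 2)


def fit_D_relaxation(curve: RelaxationCurve,
                     kernel: RelaxationKernel = HU_SPHERICAL_KERNEL,
                     **kwargs) -> float:
    """Functional wrapper: fitted diffusivity of one relaxation curve."""
    est = RelaxationDiffusivityFit(kernel=kernel, **kwargs)
    est.fit(curve)
    return est.D_


def compare_frameworks(curves: Sequence[RelaxationCurve],
                       true_params=None,
                       kernel: RelaxationKernel = HU_SPHERICAL_KERNEL,
                       master_fit_config: Optional[dict] = None) -> pd.DataFrame:
    """Relaxation-only vs master-curve D estimates on a ramp-and-hold suite.

    For each curve the hold phase is fitted with the step-response kernel
    (``D_relaxation``); the whole suite's end-of-ramp records are fitted
    with the finite-rise-time master curve (``D_master``, one value for
    the suite, repeated per row).  When ``true_params`` is given the
    per-curve ratio ``D_relaxation / D_true`` is reported against the
    normalized rise time, exposing the step-assumption bias growing with
    t_R.
    """
    from .core import RampObservation
    from .mastercurve import fit_poroelastic
    from .normalize import segment_ramp_hold

    if not curves:
        raise DomainError("need at least one curve")
    rows = []
    obs = []
    for c in curves:
        t_R, F_M, delta_M = segment_ramp_hold(c)
        est = RelaxationDiffusivityFit(kernel=kernel).fit(c)
        rows.append({
            "label": c.label, "R": c.geometry.R, "t_R": t_R,
            "delta_M": delta_M, "F_M": F_M, "D_relaxation": est.D_,
            "relaxation_flags": ";".join(est.flags_),
        })
        obs.append(RampObservation(c.geometry, t_R, delta_M, F_M))

    t_Rs = {round(o.t_R, 12) for o in obs}
    D_master = np.nan
    if len(obs) >= 3 and len(t_Rs) >= 2:
        cfg = dict(master_fit_config or {})
        cfg.setdefault("n_boot", 0)
        D_master = fit_poroelastic(obs, cfg).params.D

    out = pd.DataFrame(rows)
    out["D_master"] = D_master
    if true_params is not None:
        out["D_true"] = true_params.D
        out["tau_R"] = true_params.D * out["t_R"] / (out["R"] * out["delta_M"])
        out["ratio_relaxation"] = out["D_relaxation"] / true_params.D
        out["ratio_master"] = out["D_master"] / true_params.D
        out = out.sort_values("tau_R").reset_index(drop=True)
    return out
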