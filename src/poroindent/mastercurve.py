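"""The finite-rise-time master curve and the inverse poroelastic fit.

A ramp indentation of finite rise time ``t_R`` produces a maximum force
``F_M`` between two Hertzian limits: the undrained (instantaneous,
nu = 0.5) force at ``tau_R -> 0`` and the drained force at
``tau_R -> inf``, where ``tau_R = D t_R / (R delta_M)`` is the rise time
scaled by the pore-pressure diffusion time over the contact radius.
Mapping F_M affinely between those limits,

    F*_M(tau_R) = [F_M / ((4/3) sqrt(R) delta_M^{3/2} E) - 1/(1-nu^2)]
                  / [1/0.75 - 1/(1-nu^2)],

collapses simulated and experimental data of any geometry onto a single
dimensionless master curve, well captured empirically by

    F*(tau_R) = A exp(-b tau_R^p),   A = 12.5, b = 2.63, p = 0.12.

Matching the two expressions over a handful of ramp tests at different
velocities recovers (E, nu, D) by root-mean-square error minimization —
no relaxation (hold) data and no finite-element modeling required.  That
inverse problem is exposed both as the sklearn-style estimator
:class:`PoroelasticMasterCurveFit` and the function :func:`fit_poroelastic`.

The empirical exponential exceeds 1 for tau_R below the unit-crossing
point (~0.714) even though F*_M <= 1 by construction; forward predictions
clamp it to 1 there and fits flag (never drop) observations in that
region, where the master curve carries no rate information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .core import (
    ClampMode,
    DegenerateParameterError,
    DomainError,
    Geometry,
    MaterialParams,
    RampObservation,
    normalized_rise_time,
)

__all__ = [
    "MasterCurveCoefficients",
    "FitResult",
    "UnderdeterminedError",
    "empirical_master",
    "unit_crossing_tau",
    "normalized_max_force_definition",
    "normalized_max_force",
    "predict_FM",
    "predict_deltaM",
    "PoroelasticMasterCurveFit",
    "fit_poroelastic",
    "master_curve_table",
]


@dataclass(frozen=True)
class MasterCurveCoefficients:
    """Coefficients of the empirical master curve A*exp(-b*tau^p)."""

    A: float = 12.5
    b: float = 2.63
    p: float = 0.12

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.b > 0 and 0 < self.p < 1):
            raise DomainError("require A > 0, b > 0, 0 < p < 1")


DEFAULT_COEFFS = MasterCurveCoefficients()


class UnderdeterminedError(DomainError):
    """Too few observations / rise times to identify (E, nu, D)."""


def empirical_master(tau_R, coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
                     clamp: bool = False):
    """Empirical master curve F*(tau_R) = A exp(-b tau_R^p).

    Strictly decreasing from A at tau_R = 0 toward 0.  With ``clamp=True``
    values above 1 (tau_R below the unit-crossing point) are clamped to 1,
    which keeps forward force predictions inside the physical Hertz limits.
    """
    tau = np.asarray(tau_R, dtype=float)
    if np.any(tau < 0):
        raise DomainError("tau_R must be non-negative")
    val = coeffs.A * np.exp(-coeffs.b * tau ** coeffs.p)
    if clamp:
        val = np.minimum(val, 1.0)
    return val if val.ndim else float(val)


def unit_crossing_tau(coeffs: MasterCurveCoefficients = DEFAULT_COEFFS) -> float:
    """The tau_R at which the empirical master curve crosses 1.

    Below this point the raw exponential exceeds the physical bound
    F*_M <= 1.  Closed form: tau0 = (ln A / b)^(1/p).
    """
    return float((math.log(coeffs.A) / coeffs.b) ** (1.0 / coeffs.p))


def normalized_max_force_definition(F_M: float, F_M0: float, F_Minf: float) -> float:
    """Affine normalization F*_M = (F_M - F_Minf) / (F_M0 - F_Minf).

    ``F_M0`` is the instantaneous (tau_R = 0) and ``F_Minf`` the drained
    (tau_R = inf) limit force.
    """
    if F_M0 <= F_Minf:
        raise DegenerateParameterError(
            "instantaneous limit force must exceed the drained limit"
        )
    return (F_M - F_Minf) / (F_M0 - F_Minf)


def _hertz_prefactor(R, delta_M, E):
    return (4.0 / 3.0) * np.sqrt(R) * np.asarray(delta_M, dtype=float) ** 1.5 * E


def normalized_max_force(obs: RampObservation, E: float, nu: float) -> float:
    """Normalized maximum force of one observation given trial (E, nu).

    Substitutes the Hertz limit forces into the affine normalization:

        F*_M = [F_M / ((4/3) sqrt(R) delta_M^{3/2} E) - 1/(1-nu^2)]
               / [1/0.75 - 1/(1-nu^2)]

    The observation's own measured delta_M is used regardless of clamp
    mode.  Singular at nu = 0.5.
    """
    return _normalized_max_force_arrays(
        np.asarray(obs.F_M), obs.geometry.R, np.asarray(obs.delta_M), E, nu
    )


def _normalized_max_force_arrays(F_M, R, delta_M, E, nu):
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 0) or np.any(nu > 0.5):
        raise DomainError("nu must lie in [0, 0.5]")
    if np.any(nu == 0.5):
        raise DegenerateParameterError("normalization singular at nu = 0.5")
    if np.any(np.asarray(delta_M, dtype=float) <= 0):
        raise DomainError("delta_M must be positive")
    drained = 1.0 / (1.0 - nu ** 2)
    inst = 1.0 / 0.75
    out = (F_M / _hertz_prefactor(R, delta_M, E) - drained) / (inst - drained)
    return out if np.ndim(out) else float(out)


def predict_FM(t_R: float, delta_M: float, geometry: Geometry,
               params: MaterialParams,
               coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
               clamp: bool = True):
    """Forward model: maximum ramp force for a given rise time and depth.

    Computes tau_R, evaluates the (clamped) empirical master curve and
    inverts the Hertz-limit normalization.  With clamping the result lies
    in [F_drained, F_instantaneous].
    """
    tau = normalized_rise_time(params.D, t_R, geometry.R, delta_M)
    f_star = empirical_master(tau, coeffs, clamp=clamp)
    nu = params.nu
    drained = 1.0 / (1.0 - nu ** 2)
    inst = 1.0 / 0.75
    F = _hertz_prefactor(geometry.R, delta_M, params.E) * (
        np.asarray(f_star) * (inst - drained) + drained
    )
    return F if np.ndim(F) else float(F)


def predict_deltaM(t_R: Optional[float], F_M_target: float, geometry: Geometry,
                   params: MaterialParams,
                   coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
                   V: Optional[float] = None,
                   xtol_rel: float = 1e-10) -> float:
    """Invert the forward model for the maximum depth at fixed force.

    Solves ``predict_FM(t_R, delta_M) = F_M_target`` for delta_M by
    bracketed root finding on [1e-9 m, R].  tau_R itself depends on
    delta_M, so this is a genuine implicit solve.  In force-clamp
    protocols the rise time is not prescribed either: pass the approach
    velocity ``V`` instead of ``t_R`` and the solver uses
    ``t_R = delta_M / V`` self-consistently.
    """
    if F_M_target <= 0:
        raise DomainError("target force must be positive")
    if (t_R is None) == (V is None):
        raise DomainError("provide exactly one of t_R or V")

    def f(delta):
        tr = delta / V if V is not None else t_R
        return predict_FM(tr, delta, geometry, params, coeffs) - F_M_target

    lo, hi = 1e-9, geometry.R
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise DomainError(
            f"no depth in [1e-9, R={geometry.R}] m reaches F = {F_M_target} N"
        )
    return float(optimize.brentq(f, lo, hi, rtol=xtol_rel))


@dataclass
class FitResult:
    """Outcome of a master-curve fit: parameters, residual, diagnostics."""

    params: MaterialParams
    rms: float
    n_obs: int
    tau_R: np.ndarray
    F_star: np.ndarray
    uncertainty: dict
    flags: list

    def summary(self) -> str:
        u = self.uncertainty or {}
        def pm(key):
            return f" +/- {u[key]:.3g}" if key in u else ""
        return (
            f"E  = {self.params.E / 1e3:.4g}{pm('E_kPa')} kPa\n"
            f"nu = {self.params.nu:.4g}{pm('nu')}\n"
            f"D  = {self.params.D:.4g}{pm('D')} m^2/s\n"
            f"rms = {self.rms:.4g} over {self.n_obs} observations\n"
            f"flags: {', '.join(self.flags) if self.flags else 'none'}"
        )


def _obs_arrays(observations: Sequence[RampObservation]):
    R = np.array([o.geometry.R for o in observations])
    t_R = np.array([o.t_R for o in observations])
    delta_M = np.array([o.delta_M for o in observations])
    F_M = np.array([o.F_M for o in observations])
    return R, t_R, delta_M, F_M


class PoroelasticMasterCurveFit(BaseEstimator):
    """Estimate (E, nu, D) of a poroelastic material from ramp observations.

    Minimizes the root-mean-square mismatch between the Hertz-normalized
    maximum forces of the observations and the empirical master curve
    evaluated at their normalized rise times.  The RMS surface is cheap
    but multimodal in (nu, D), so a vectorized coarse grid seeds a
    derivative-free Nelder-Mead refinement in (log E, logit nu, log D).

    Parameters
    ----------
    coeffs : MasterCurveCoefficients
        Master-curve constants; defaults to the calibrated values.
    nu_bounds : tuple
        Search interval for the Poisson ratio, default (0.0, 0.49); 0.5 is
        excluded because the normalization is singular there.
    n_nu_grid, n_D_grid : int
        Coarse-grid resolution over (nu, D).  The D grid spans
        ``D_span_decades`` decades either side of a scaling initial guess
        D0 ~ R delta_M/t_R (the value that puts a mid-range observation at
        tau_R = 1).  E never needs a grid: the normalized force is affine
        in 1/E, so the optimal E is profiled out in closed form.
    clamp : bool
        Clamp the empirical curve at 1 (its physical bound) inside the
        objective and forward predictions.
    n_boot : int
        Bootstrap resamples (over observations) for parameter standard
        deviations; 0 disables.
    weights : array-like or None
        Optional per-observation residual weights (default unweighted).
    random_state : int or None
        Seed for the bootstrap.

    Attributes
    ----------
    E_, nu_, D_ : float
        Point estimates (Pa, -, m^2/s).
    rms_ : float
        Residual RMS at the optimum.
    tau_R_, F_star_ : ndarray
        Per-observation normalized rise times and normalized forces.
    uncertainty_ : dict
        Bootstrap standard deviations (keys ``E``, ``nu``, ``D``), empty
        when n_boot = 0.
    flags_ : list of str
        Warnings: observations below the master curve's unit crossing,
        optimizer non-convergence.
    result_ : FitResult
        The full structured result.
    """

    def __init__(self, coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
                 nu_bounds: tuple = (0.0, 0.49), n_nu_grid: int = 251,
                 n_D_grid: int = 121, D_span_decades: float = 3.0,
                 clamp: bool = True, n_boot: int = 200,
                 weights=None, random_state: Optional[int] = None):
        self.coeffs = coeffs
        self.nu_bounds = nu_bounds
        self.n_nu_grid = n_nu_grid
        self.n_D_grid = n_D_grid
        self.D_span_decades = D_span_decades
        self.clamp = clamp
        self.n_boot = n_boot
        self.weights = weights
        self.random_state = random_state

    # -- data marshalling -------------------------------------------------
    @staticmethod
    def _as_observations(X) -> list:
        if isinstance(X, pd.DataFrame):
            obs = []
            for _, row in X.iterrows():
                mode = ClampMode(row["mode"]) if "mode" in row else ClampMode.DISPLACEMENT
                obs.append(RampObservation(
                    Geometry(float(row["R"])), float(row["t_R"]),
                    float(row["delta_M"]), float(row["F_M"]), mode=mode,
                    label=str(row.get("label", "")),
                ))
            return obs
        obs = list(X)
        if not all(isinstance(o, RampObservation) for o in obs):
            raise DomainError(
                "X must be a DataFrame with columns R/t_R/delta_M/F_M (SI) "
                "or a sequence of RampObservation"
            )
        return obs

    # -- objective --------------------------------------------------------
    def _residuals(self, E, nu, D, R, t_R, delta_M, F_M):
        """Vectorized residual array, broadcasting over parameter grids."""
        tau = D * t_R / (R * delta_M)
        emp = self.coeffs.A * np.exp(-self.coeffs.b * tau ** self.coeffs.p)
        if self.clamp:
            emp = np.minimum(emp, 1.0)
        data = _normalized_max_force_arrays(F_M, R, delta_M, E, nu)
        return data - emp

    def _rms(self, E, nu, D, arrays, w):
        res = self._residuals(E, nu, D, *arrays)
        return np.sqrt(np.sum(w * res ** 2, axis=-1) / np.sum(w))

    def _profiled(self, nu, D, arrays, w):
        """Optimal E (closed form) and RMS at given (nu, D) grids.

        The normalized data force is affine in s = 1/E, so the weighted
        least-squares s* is closed-form per (nu, D); broadcasting shapes
        (..., 1) for nu/D against the trailing observation axis.
        """
        R, t_R, delta_M, F_M = arrays
        nu = np.asarray(nu, dtype=float)
        D = np.asarray(D, dtype=float)
        drained = 1.0 / (1.0 - nu ** 2)
        inst = 1.0 / 0.75
        denom = inst - drained
        tau = D * t_R / (R * delta_M)
        emp = self.coeffs.A * np.exp(-self.coeffs.b * tau ** self.coeffs.p)
        if self.clamp:
            emp = np.minimum(emp, 1.0)
        pref = (4.0 / 3.0) * np.sqrt(R) * delta_M ** 1.5
        alpha = (F_M / pref) / denom
        beta = -drained / denom - emp
        s = -np.sum(w * alpha * beta, axis=-1) / np.sum(w * alpha ** 2, axis=-1)
        s = np.maximum(s, 1e-300)  # nonphysical (E<=0) points get huge E, large rms
        res = alpha * s[..., None] + beta
        rms = np.sqrt(np.sum(w * res ** 2, axis=-1) / np.sum(w))
        return 1.0 / s, rms

    def _point_fit(self, arrays, w, x0=None):
        """Grid seed (unless x0 given) + Nelder-Mead on the E-profiled (nu, D)
        surface. Returns (E, nu, D, rms, converged)."""
        R, t_R, delta_M, F_M = arrays
        nu_lo, nu_hi = self.nu_bounds
        nu_cap = min(nu_hi, 0.4999)
        if x0 is None:
            # scaling guess: D0 puts the median observation at tau_R = 1
            D0 = float(np.median(R * delta_M / t_R))
            D_grid = np.geomspace(D0 * 10 ** -self.D_span_decades,
                                  D0 * 10 ** self.D_span_decades, self.n_D_grid)
            nu_grid = np.linspace(nu_lo, nu_cap, self.n_nu_grid)
            _, rms = self._profiled(nu_grid[:, None, None], D_grid[None, :, None],
                                    arrays, w)
            # per-nu-row zoom on D: the surface can hold needle-thin basins
            # (exact-data fits at high nu are sharp in both nu and D), so
            # refine each row's best D by iterated bracketing before ranking
            logD = np.log(D_grid)
            jbest = np.argmin(rms, axis=1)
            lo = logD[np.maximum(jbest - 1, 0)]
            hi = logD[np.minimum(jbest + 1, len(D_grid) - 1)]
            frac = np.linspace(0.0, 1.0, 9)
            for _ in range(6):
                zoom = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
                _, rz = self._profiled(nu_grid[:, None, None],
                                       np.exp(zoom)[..., None], arrays, w)
                j = np.argmin(rz, axis=1)
                center = np.take_along_axis(zoom, j[:, None], 1)[:, 0]
                width = (hi - lo) / 4.0
                lo, hi = center - width, center + width
            row_rms = rz.min(axis=1)
            row_D = np.exp(center)
            # multiple refinement seeds from well-separated nu neighbourhoods
            starts = []
            min_sep = max(1, self.n_nu_grid // 25)
            for i in np.argsort(row_rms):
                if any(abs(int(i) - j) < min_sep for j in starts):
                    continue
                starts.append(int(i))
                if len(starts) >= 3:
                    break
            seeds = [(float(nu_grid[i]), float(row_D[i])) for i in starts]
        else:
            _, nu0, D0 = x0
            seeds = [(min(max(nu0, nu_lo), nu_cap), D0)]

        span = nu_cap - nu_lo
        def to_nu(s):
            return nu_lo + span / (1.0 + np.exp(-s))
        def to_s(nu):
            f = np.clip((nu - nu_lo) / span, 1e-9, 1 - 1e-9)
            return math.log(f / (1.0 - f))

        def obj(x):
            _, r = self._profiled(to_nu(x[0]), np.exp(x[1]), arrays, w)
            return float(r)

        best = None
        for nu0, D0 in seeds:
            x_start = np.array([to_s(nu0), math.log(D0)])
            for _ in range(2):  # restart once: simplex refinement can stall early
                res = optimize.minimize(
                    obj, x_start, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000,
                             "maxfev": 4000},
                )
                if best is None or res.fun < best.fun:
                    best = res
                x_start = res.x
        nu = float(to_nu(best.x[0]))
        D = float(np.exp(best.x[1]))
        E, rms = self._profiled(nu, D, arrays, w)
        return float(E), nu, D, float(rms), bool(best.success)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None):
        obs = self._as_observations(X)
        if len(obs) < 3:
            raise UnderdeterminedError("need at least 3 observations")
        arrays = _obs_arrays(obs)
        R, t_R, delta_M, F_M = arrays
        if np.unique(t_R).size < 2:
            raise UnderdeterminedError(
                "all observations share one rise time: D is unidentifiable"
            )
        w = (np.ones_like(F_M) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if w.shape != F_M.shape or np.any(w < 0) or not np.any(w > 0):
            raise DomainError("weights must be non-negative, one per observation")

        E, nu, D, rms, converged = self._point_fit(arrays, w)
        flags = []
        if not converged:
            flags.append("optimizer_not_converged")

        tau = normalized_rise_time(D, t_R, R, delta_M)
        tau0 = unit_crossing_tau(self.coeffs)
        n_below = int(np.sum(tau < tau0))
        if n_below:
            flags.append(
                f"{n_below} observation(s) below master-curve unit crossing "
                f"(tau_R < {tau0:.3g}): rate information saturated there"
            )

        uncertainty = {}
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            n = len(obs)
            samples = []
            attempts = 0
            while len(samples) < self.n_boot and attempts < 20 * self.n_boot:
                attempts += 1
                idx = rng.integers(0, n, size=n)
                if np.unique(t_R[idx]).size < 2:
                    continue
                sub = tuple(a[idx] for a in arrays)
                Eb, nub, Db, _, _ = self._point_fit(sub, w[idx], x0=(E, nu, D))
                samples.append((Eb, nub, Db))
            if samples:
                s = np.array(samples)
                uncertainty = {
                    "E": float(np.std(s[:, 0], ddof=1)),
                    "E_kPa": float(np.std(s[:, 0], ddof=1) / 1e3),
                    "nu": float(np.std(s[:, 1], ddof=1)),
                    "D": float(np.std(s[:, 2], ddof=1)),
                }

        self.E_, self.nu_, self.D_ = E, nu, D
        self.rms_ = rms
        self.tau_R_ = tau
        self.F_star_ = np.array([
            _normalized_max_force_arrays(F_M[i], R[i], delta_M[i], E, nu)
            for i in range(len(obs))
        ])
        self.uncertainty_ = uncertainty
        self.flags_ = flags
        self.n_obs_ = len(obs)
        self.observations_ = obs
        self.result_ = FitResult(
            params=MaterialParams(E, nu, D), rms=rms, n_obs=len(obs),
            tau_R=self.tau_R_, F_star=self.F_star_,
            uncertainty=uncertainty, flags=flags,
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted maximum force (N) for each observation's (R, t_R, delta_M)."""
        if not hasattr(self, "result_"):
            raise DomainError("estimator is not fitted")
        obs = self._as_observations(X)
        params = self.result_.params
        return np.array([
            predict_FM(o.t_R, o.delta_M, o.geometry, params, self.coeffs,
                       clamp=self.clamp)
            for o in obs
        ])


def fit_poroelastic(observations, config: Optional[dict] = None) -> FitResult:
    """Functional wrapper over :class:`PoroelasticMasterCurveFit`.

    ``config`` keys map to estimator parameters (e.g. ``n_boot``,
    ``nu_bounds``, ``clamp``, ``random_state``, ``weights``).
    """
    est = PoroelasticMasterCurveFit(**(config or {}))
    est.fit(observations)
    return est.result_


def master_curve_table(fit: FitResult,
                       coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
                       clamp: bool = True) -> pd.DataFrame:
    """Plottable overlay of data vs empirical master curve, one row per observation."""
    tau = np.asarray(fit.tau_R, dtype=float)
    return pd.DataFrame({
        "tau_R": tau,
        "F_star_data": np.asarray(fit.F_star, dtype=float),
        "F_star_empirical": empirical_master(tau, coeffs, clamp=clamp),
    })
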