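"""Synthetic ramp-and-hold indentation experiments.

Two deliberately independent forward models stand in for instruments and
finite-element simulation:

1. :func:`simulate_ramp_suite` produces end-of-ramp records
   (R, t_R, delta_M, F_M) directly from the master-curve forward model —
   exactly self-consistent with the inverse fit, hence the tool for
   parameter-recovery studies.

2. :func:`simulate_relaxation_curve` produces full force-time curves from
   a hereditary-integral surrogate: with h(t) = delta(t)^{3/2} and a
   linear ramp delta(t) = delta_M min(t, t_R)/t_R,

       F(t) = C_d h(t) + (C_i - C_d) * int_0^t g(D (t-u)/a(t)^2) h'(u) du,

   where C_d = (4/3) sqrt(R) E/(1-nu^2), C_i = (4/3) sqrt(R) E/0.75 and
   a(t) = sqrt(R delta(t)).  The kernel argument freezes the diffusion
   length at the *current* contact radius — an approximation, but one that
   guarantees the exact poroelastic limits F(0) = 0, F(t_R) -> undrained
   Hertz force as t_R -> 0, and F(inf) -> drained Hertz force, and
   reproduces the effective-velocity collapse behavior.  It is used for
   normalization/collapse tests and as a quasi-independent cross-check of
   the master-curve route; it is not derived from it.

Noise is multiplicative Gaussian on force (optional additive depth noise),
applied after all deterministic solves, never inside root finds, and fully
determined by the protocol seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    ClampMode,
    DomainError,
    Geometry,
    MaterialParams,
    RampObservation,
    RelaxationCurve,
)
from .mastercurve import (
    DEFAULT_COEFFS,
    MasterCurveCoefficients,
    predict_FM,
    predict_deltaM,
)
from .relaxation import HU_SPHERICAL_KERNEL, RelaxationKernel

__all__ = [
    "NoiseSpec",
    "ProtocolSpec",
    "PROTOCOL_PRESETS",
    "emulate_paper_protocols",
    "simulate_ramp_suite",
    "simulate_relaxation_curve",
    "simulate_relaxation_suite",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative-Gaussian force noise and additive depth noise."""

    sigma_F_rel: float = 0.0
    sigma_delta: float = 0.0
    kind: str = "multiplicative-gaussian"

    def __post_init__(self) -> None:
        if self.sigma_F_rel < 0 or self.sigma_delta < 0:
            raise DomainError("noise sigmas must be non-negative")

    @property
    def active(self) -> bool:
        return self.sigma_F_rel > 0 or self.sigma_delta > 0


@dataclass(frozen=True)
class ProtocolSpec:
    """An indentation campaign: clamp mode, geometry, targets and rates.

    ``targets`` are maximum forces (N) in force clamp, maximum depths (m)
    in displacement clamp.  Either approach ``velocities`` (m/s; natural
    for force clamp, where t_R emerges) or ``rise_times`` (s; natural for
    displacement clamp) must be given.  ``R`` may be a single radius or a
    sequence (suites mixing indenter sizes).
    """

    mode: ClampMode
    R: Union[float, Sequence[float]]
    targets: Sequence[float]
    velocities: Optional[Sequence[float]] = None
    rise_times: Optional[Sequence[float]] = None
    t_hold: Optional[float] = None
    sampling_rate: float = 10.0
    noise: NoiseSpec = NoiseSpec()
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not len(self.targets):
            raise DomainError("targets must be non-empty")
        if (self.velocities is None) == (self.rise_times is None):
            raise DomainError("provide exactly one of velocities or rise_times")
        rates = self.velocities if self.velocities is not None else self.rise_times
        if not len(rates):
            raise DomainError("rate list must be non-empty")
        if self.noise.active and self.seed is None:
            raise DomainError("a seed is required when noise is active")

    @property
    def radii(self) -> tuple:
        if np.ndim(self.R) == 0:
            return (float(self.R),)
        return tuple(float(r) for r in self.R)


# Protocol constants of the two experimental campaigns emulated here:
# an AFM force-clamp series on soft 0.6% agarose with a 25 um bead, and
# macro-scale displacement-clamp series on agarose/polyacrylamide gels
# with mm-scale steel indenters.
_UM = 1e-6
_MM = 1e-3
PROTOCOL_PRESETS = {
    "afm_agarose06": ProtocolSpec(
        mode=ClampMode.FORCE, R=25 * _UM,
        targets=(500e-9, 1000e-9, 1600e-9),
        velocities=tuple(v * _UM for v in (320, 160, 80, 40, 20, 10, 5, 1)),
        t_hold=30.0, sampling_rate=1000.0, label="afm_agarose06",
    ),
    "macro_agarose06": ProtocolSpec(
        mode=ClampMode.DISPLACEMENT, R=7.5 * _MM, targets=(3 * _MM,),
        rise_times=(3.0, 30.0, 120.0, 300.0),
        t_hold=3600.0, sampling_rate=10.0, label="macro_agarose06",
    ),
    "macro_agarose1_R5": ProtocolSpec(
        mode=ClampMode.DISPLACEMENT, R=5 * _MM, targets=(2 * _MM,),
        rise_times=(50.0, 150.0, 200.0, 400.0),
        t_hold=3600.0, sampling_rate=10.0, label="macro_agarose1_R5",
    ),
    "macro_agarose1_R5R10": ProtocolSpec(
        mode=ClampMode.DISPLACEMENT, R=(5 * _MM, 10 * _MM),
        targets=(0.5 * _MM, 1 * _MM, 1.5 * _MM),
        rise_times=(100.0, 200.0, 300.0),
        t_hold=3600.0, sampling_rate=10.0, label="macro_agarose1_R5R10",
    ),
    "macro_paam": ProtocolSpec(
        mode=ClampMode.DISPLACEMENT, R=7.5 * _MM,
        targets=(1 * _MM, 2 * _MM, 3 * _MM),
        rise_times=(1000.0, 2000.0, 3000.0),
        t_hold=36000.0, sampling_rate=10.0, label="macro_paam",
    ),
}


def emulate_paper_protocols(name: str) -> ProtocolSpec:
    """A named preset protocol (see PROTOCOL_PRESETS for the catalogue)."""
    try:
        return PROTOCOL_PRESETS[name]
    except KeyError:
        raise DomainError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None


def simulate_ramp_suite(params: MaterialParams, protocol: ProtocolSpec,
                        coeffs: MasterCurveCoefficients = DEFAULT_COEFFS,
                        ) -> list:
    """Generate one RampObservation per (R, target, rate) combination.

    Displacement clamp: F_M from the forward master-curve model at each
    (delta_M, t_R).  Force clamp: delta_M from the implicit inversion with
    t_R = delta_M / V resolved self-consistently inside the root solve.
    Noise is applied after the deterministic solve; identical
    (params, protocol, seed) give identical records.
    """
    rng = np.random.default_rng(protocol.seed)
    records = []
    for R in protocol.radii:
        geom = Geometry(R)
        for target in protocol.targets:
            if protocol.mode is ClampMode.DISPLACEMENT:
                rates = (protocol.rise_times if protocol.rise_times is not None
                         else [target / v for v in protocol.velocities])
                for t_R in rates:
                    F_M = predict_FM(t_R, target, geom, params, coeffs)
                    records.append((geom, float(t_R), float(target), float(F_M)))
            else:
                if protocol.velocities is None:
                    raise DomainError("force clamp requires approach velocities")
                for V in protocol.velocities:
                    try:
                        delta_M = predict_deltaM(None, target, geom, params,
                                                 coeffs, V=V)
                    except DomainError:
                        import warnings
                        warnings.warn(
                            f"skipping record R={R}, F={target}, V={V}: "
                            "depth solve failed", stacklevel=2)
                        continue
                    records.append((geom, delta_M / V, delta_M, float(target)))

    observations = []
    for geom, t_R, delta_M, F_M in records:
        if protocol.noise.active:
            F_M = F_M * (1.0 + protocol.noise.sigma_F_rel * rng.standard_normal())
            delta_M = delta_M + protocol.noise.sigma_delta * rng.standard_normal()
            F_M = max(F_M, 1e-15)
            delta_M = max(delta_M, 1e-12)
        mode = protocol.mode
        observations.append(RampObservation(geom, t_R, delta_M, F_M, mode=mode,
                                            label=protocol.label))
    return observations


def _default_grid(t_R: float, t_hold: float, n_ramp: int, n_hold: int) -> np.ndarray:
    ramp = np.linspace(0.0, t_R, n_ramp)
    # log spacing in the hold: relaxation spans decades
    hold = t_R + np.geomspace(t_hold / 10 ** 4, t_hold, n_hold)
    return np.concatenate([ramp, hold])


def simulate_relaxation_curve(params: MaterialParams, geometry: Geometry,
                              delta_M: float, t_R: float,
                              t_grid: Optional[np.ndarray] = None,
                              kernel: RelaxationKernel = HU_SPHERICAL_KERNEL,
                              noise: NoiseSpec = NoiseSpec(),
                              seed: Optional[int] = None,
                              t_hold: Optional[float] = None,
                              n_ramp: int = 400, n_hold: int = 1600,
                              label: str = "") -> RelaxationCurve:
    """Hereditary-integral surrogate of a ramp-and-hold force-time curve.

    See the module docstring for the model.  The default grid is linear
    over the ramp and log-spaced over a hold of duration ``t_hold``
    (default 20 contact-diffusion times, enough to approach the drained
    limit); a user grid must be strictly increasing, start at 0 and will
    have the ramp endpoint inserted if absent.  Trapezoidal quadrature on
    the grid.
    """
    if delta_M <= 0 or t_R <= 0:
        raise DomainError("delta_M and t_R must be positive")
    if t_grid is None:
        if t_hold is None:
            t_hold = 20.0 * geometry.R * delta_M / params.D
        t_grid = _default_grid(t_R, t_hold, n_ramp, n_hold)
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if np.any(np.diff(t_grid) <= 0):
            raise DomainError("t_grid must be strictly increasing")
        if t_R < t_grid[-1] and not np.any(np.isclose(t_grid, t_R)):
            t_grid = np.sort(np.append(t_grid, t_R))

    R, E, nu, D = geometry.R, params.E, params.nu, params.D
    C_d = (4.0 / 3.0) * np.sqrt(R) * E / (1.0 - nu ** 2)
    C_i = (4.0 / 3.0) * np.sqrt(R) * E / 0.75

    delta = delta_M * np.minimum(t_grid, t_R) / t_R
    h = delta ** 1.5
    rate = 1.5 * np.sqrt(delta) * (delta_M / t_R)  # dh/dt during the ramp
    ramp_mask = t_grid <= t_R
    u = t_grid[ramp_mask]
    hdot = rate[ramp_mask]

    F = np.empty_like(t_grid)
    for j, t in enumerate(t_grid):
        if t <= 0:
            F[j] = 0.0
            continue
        a2 = R * delta[j]
        sel = u <= t
        uu, dd = u[sel], hdot[sel]
        integrand = kernel.g(D * (t - uu) / a2) * dd
        conv = np.trapezoid(integrand, uu) if uu.size > 1 else 0.0
        F[j] = C_d * h[j] + (C_i - C_d) * conv

    delta_channel = delta.copy()
    if noise.active:
        rng = np.random.default_rng(seed)
        if noise.sigma_F_rel > 0:
            F = F * (1.0 + noise.sigma_F_rel * rng.standard_normal(F.shape))
        if noise.sigma_delta > 0:
            delta_channel = delta_channel + noise.sigma_delta * rng.standard_normal(F.shape)

    i_end = int(np.argmin(np.abs(t_grid - t_R)))
    return RelaxationCurve(
        t=t_grid, F=F, delta=delta_channel, geometry=geometry, t_R=t_R,
        F_M=float(F[i_end]), delta_M=float(delta_M), label=label,
    )


def simulate_relaxation_suite(params: MaterialParams, protocol: ProtocolSpec,
                              kernel: RelaxationKernel = HU_SPHERICAL_KERNEL,
                              n_ramp: int = 400, n_hold: int = 1600) -> list:
    """Full force-time curves for a displacement-clamp protocol."""
    if protocol.mode is not ClampMode.DISPLACEMENT:
        raise DomainError("curve suites are generated for displacement clamp")
    curves = []
    k = 0
    for R in protocol.radii:
        geom = Geometry(R)
        for delta_M in protocol.targets:
            rates = (protocol.rise_times if protocol.rise_times is not None
                     else [delta_M / v for v in protocol.velocities])
            for t_R in rates:
                seed = None if protocol.seed is None else protocol.seed + k
                curves.append(simulate_relaxation_curve(
                    params, geom, float(delta_M), float(t_R), kernel=kernel,
                    noise=protocol.noise, seed=seed, t_hold=protocol.t_hold,
                    n_ramp=n_ramp, n_hold=n_hold,
                    label=f"{protocol.label}[{k}]",
                ))
                k += 1
    return curves
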