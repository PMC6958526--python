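"""Domain types and contact-mechanics primitives for poroelastic indentation.

All quantities are strict SI internally (m, s, N, Pa, m^2/s).  Unit
conversion happens once, at the I/O boundary (:mod:`poroindent.io`); the
functions here assume consistent SI inputs and are written so that any
consistent rescaling of units leaves dimensionless outputs unchanged.

The physical picture: a rigid sphere of radius ``R`` is pressed a depth
``delta`` into a fluid-saturated elastic half-space.  Deformation
pressurizes the interstitial fluid, which relaxes by diffusing through the
pores with diffusivity ``D``.  The contact radius ``a = sqrt(R*delta)`` is
the length scale of pore-pressure propagation, so the characteristic
relaxation time is ``a**2 / D`` and the dimensionless rise time of a ramp
of duration ``t_R`` is ``tau_R = D * t_R / (R * delta_M)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ClampMode",
    "Geometry",
    "MaterialParams",
    "RampObservation",
    "RelaxationCurve",
    "contact_radius",
    "rise_time",
    "approach_velocity",
    "effective_velocity",
    "normalized_rise_time",
    "hertz_force",
    "limit_forces",
    "permeability_from_diffusivity",
    "validity_flags",
]

# Incompressible (undrained) Poisson ratio: at instantaneous loading the
# fluid has no time to redistribute, so the composite responds with nu=0.5.
NU_UNDRAINED = 0.5

# Hertz validity bound delta/R and thin-sample bound a/h for warning flags.
HERTZ_DEPTH_RATIO = 0.6
THIN_SAMPLE_RATIO = 0.1


class ClampMode(str, enum.Enum):
    """Which quantity the instrument holds at the end of the ramp.

    AFM force-relaxation tests prescribe the maximum force (``force_clamp``);
    macro-scale indenters prescribe the maximum depth (``displacement_clamp``).
    """

    FORCE = "force_clamp"
    DISPLACEMENT = "displacement_clamp"


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class DegenerateParameterError(DomainError):
    """Parameters make the requested relation singular (e.g. nu = 0.5)."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


@dataclass(frozen=True)
class Geometry:
    """Indenter/sample geometry. ``R`` indenter radius, ``h`` sample thickness (m)."""

    R: float
    h: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        _require(self.R > 0, f"indenter radius must be positive, got {self.R}")
        if self.h is not None:
            _require(self.h > 0, f"sample thickness must be positive, got {self.h}")


@dataclass(frozen=True)
class MaterialParams:
    """Drained linear isotropic poroelastic material.

    Parameters
    ----------
    E : float
        Drained elastic (Young) modulus, Pa.
    nu : float
        Drained Poisson ratio; must lie in ``[0, 0.5)``.  The undrained
        limit 0.5 is excluded because the force-normalization denominator
        vanishes there.  Negative (auxetic) ratios are rejected unless
        ``allow_auxetic`` is set.
    D : float
        Poroelastic diffusion coefficient, m^2/s.
    """

    E: float
    nu: float
    D: float
    allow_auxetic: bool = False

    def __post_init__(self) -> None:
        _require(self.E > 0, f"elastic modulus must be positive, got {self.E}")
        _require(self.D > 0, f"diffusion coefficient must be positive, got {self.D}")
        lo = -1.0 if self.allow_auxetic else 0.0
        _require(
            lo <= self.nu < NU_UNDRAINED,
            f"Poisson ratio must lie in [{lo}, 0.5), got {self.nu}",
        )

    @property
    def shear_modulus(self) -> float:
        """G = E / (2 (1 + nu)), Pa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def permeability(self) -> float:
        """Hydraulic permeability K (m^4 N^-1 s^-1); see permeability_from_diffusivity."""
        return permeability_from_diffusivity(self.E, self.nu, self.D)


@dataclass(frozen=True)
class RampObservation:
    """A single ramp test: one (R, t_R, delta_M, F_M) point.

    The unit of data for master-curve fitting.  ``V`` is the approach
    velocity ``delta_M / t_R``; when supplied explicitly it must be
    consistent with ``delta_M`` and ``t_R`` to 1e-9 relative.
    """

    geometry: Geometry
    t_R: float
    delta_M: float
    F_M: float
    mode: ClampMode = ClampMode.DISPLACEMENT
    V: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        _require(self.t_R > 0, f"rise time must be positive, got {self.t_R}")
        _require(self.delta_M > 0, f"maximum depth must be positive, got {self.delta_M}")
        _require(self.F_M > 0, f"maximum force must be positive, got {self.F_M}")
        if self.V is None:
            object.__setattr__(self, "V", self.delta_M / self.t_R)
        else:
            _require(
                math.isclose(self.V * self.t_R, self.delta_M, rel_tol=1e-9),
                f"V*t_R = {self.V * self.t_R!r} inconsistent with delta_M = {self.delta_M!r}",
            )

    @classmethod
    def from_velocity(
        cls,
        geometry: Geometry,
        V: float,
        delta_M: float,
        F_M: float,
        mode: ClampMode = ClampMode.DISPLACEMENT,
        label: str = "",
    ) -> "RampObservation":
        _require(V > 0, f"approach velocity must be positive, got {V}")
        return cls(geometry, delta_M / V, delta_M, F_M, mode=mode, V=V, label=label)

    @property
    def effective_velocity(self) -> float:
        return effective_velocity(self.geometry.R, self.delta_M, self.t_R)


@dataclass
class RelaxationCurve:
    """Sampled force-time record of a ramp-and-hold test.

    ``t`` must be strictly increasing; ``delta`` is the optional depth
    channel.  ``meta`` carries the protocol scalars (SI): geometry, t_R,
    F_M, delta_M and, once estimated, F_inf.
    """

    t: np.ndarray
    F: np.ndarray
    delta: Optional[np.ndarray] = None
    geometry: Optional[Geometry] = None
    t_R: Optional[float] = None
    F_M: Optional[float] = None
    F_inf: Optional[float] = None
    delta_M: Optional[float] = None
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise DomainError("t and F must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise DomainError("sample times must be strictly increasing")
        if self.delta is not None:
            self.delta = np.asarray(self.delta, dtype=float)
            if self.delta.shape != self.t.shape:
                raise DomainError("depth channel length must match time")
        if self.F_inf is not None and self.F_M is not None:
            _require(self.F_inf <= self.F_M, "F_inf must not exceed F_M")

    def __len__(self) -> int:
        return int(self.t.size)


def contact_radius(R, delta):
    """Hertzian contact radius a = sqrt(R * delta) for a sphere at small depth."""
    R = np.asarray(R, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(R <= 0) or np.any(delta < 0):
        raise DomainError("contact_radius requires R > 0 and delta >= 0")
    return np.sqrt(R * delta)


def rise_time(delta_M: float, V: float) -> float:
    """Ramp duration t_R = delta_M / V at constant approach velocity V."""
    _require(delta_M > 0, f"delta_M must be positive, got {delta_M}")
    _require(V > 0, f"approach velocity must be positive, got {V}")
    return delta_M / V


def approach_velocity(delta_M: float, t_R: float) -> float:
    """Constant approach velocity V = delta_M / t_R."""
    _require(delta_M > 0, f"delta_M must be positive, got {delta_M}")
    _require(t_R > 0, f"rise time must be positive, got {t_R}")
    return delta_M / t_R


def effective_velocity(R, delta_M, t_R):
    """Effective approach velocity V_eff = sqrt(R * delta_M) / t_R.

    Normalized relaxation curves of a given material collapse only when
    V_eff (equivalently the ramp's span of the poroelastic length scale
    per unit time) matches across tests.
    """
    R = np.asarray(R, dtype=float)
    delta_M = np.asarray(delta_M, dtype=float)
    t_R = np.asarray(t_R, dtype=float)
    if np.any(R <= 0) or np.any(delta_M <= 0) or np.any(t_R <= 0):
        raise DomainError("effective_velocity requires positive R, delta_M, t_R")
    return np.sqrt(R * delta_M) / t_R


def normalized_rise_time(D, t_R, R, delta_M):
    """Dimensionless rise time tau_R = D * t_R / (R * delta_M).

    The ratio of ramp duration to the pore-pressure diffusion time over the
    contact radius ``a^2/D = R*delta_M/D``.  ``t_R = 0`` is admitted as the
    instantaneous-ramp limit and maps to 0.
    """
    D = np.asarray(D, dtype=float)
    t_R = np.asarray(t_R, dtype=float)
    R = np.asarray(R, dtype=float)
    delta_M = np.asarray(delta_M, dtype=float)
    if np.any(D <= 0) or np.any(R <= 0) or np.any(delta_M <= 0) or np.any(t_R < 0):
        raise DomainError(
            "normalized_rise_time requires D, R, delta_M > 0 and t_R >= 0"
        )
    return D * t_R / (R * delta_M)


def hertz_force(R, delta, E, nu):
    """Hertz contact force for a rigid sphere on an elastic half-space.

    F = (4/3) * sqrt(R) * delta^{3/2} * E / (1 - nu^2)
    """
    R = np.asarray(R, dtype=float)
    delta = np.asarray(delta, dtype=float)
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(R < 0) or np.any(delta < 0):
        raise DomainError("hertz_force requires R, delta >= 0")
    if np.any(nu < 0) or np.any(nu >= 1):
        raise DomainError("hertz_force requires 0 <= nu < 1")
    return (4.0 / 3.0) * np.sqrt(R) * delta ** 1.5 * E / (1.0 - nu ** 2)


def limit_forces(R, delta_M, E, nu):
    """Instantaneous (undrained) and drained Hertz force limits.

    Instantaneous loading leaves no time for fluid redistribution, so the
    response is incompressible (nu = 0.5, denominator 0.75); full drainage
    responds with the material's drained nu.  Returns
    ``(F_instantaneous, F_drained)`` with F_instantaneous > F_drained for
    all nu in [0, 0.5).
    """
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr < 0) or np.any(nu_arr >= NU_UNDRAINED):
        raise DomainError("limit_forces requires 0 <= nu < 0.5")
    f_inst = hertz_force(R, delta_M, E, NU_UNDRAINED)
    f_drained = hertz_force(R, delta_M, E, nu)
    return f_inst, f_drained


def permeability_from_diffusivity(E: float, nu: float, D: float) -> float:
    """Hydraulic permeability K from the poroelastic diffusivity.

    Linear isotropic poroelasticity ties the three transport/elastic
    parameters through D / (K E) = (1 - nu) / ((1 - 2 nu)(1 + nu)), i.e.
    K = D (1 - 2 nu)(1 + nu) / (E (1 - nu)).  The relation is singular at
    nu = 0.5 (incompressible limit), which raises rather than returning 0.
    """
    _require(E > 0, f"E must be positive, got {E}")
    _require(D > 0, f"D must be positive, got {D}")
    if not 0 <= nu < NU_UNDRAINED:
        if nu == NU_UNDRAINED:
            raise DegenerateParameterError(
                "permeability relation is singular at nu = 0.5"
            )
        raise DomainError(f"nu must lie in [0, 0.5), got {nu}")
    return D * (1.0 - 2.0 * nu) * (1.0 + nu) / (E * (1.0 - nu))


def validity_flags(geometry: Geometry, delta_M: float) -> set:
    """Warning flags for regimes where the Hertz half-space model degrades.

    ``hertz_regime_exceeded``: delta_M / R > 0.6 (large-deformation regime);
    ``thin_sample``: contact radius over thickness a/h > 0.1 (substrate
    effects).  Flags warn, never raise.
    """
    flags = set()
    if delta_M / geometry.R > HERTZ_DEPTH_RATIO:
        flags.add("hertz_regime_exceeded")
    if geometry.h is not None:
        a = contact_radius(geometry.R, delta_M)
        if a / geometry.h > THIN_SAMPLE_RATIO:
            flags.add("thin_sample")
    return flags
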