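"""Closed-form transport physics for nanoparticle diffusion through barriers.

All quantities are SI internally, with the two conventional exceptions used
throughout the package: concentrations are g/m^3 (numerically equal to mg/L)
and masses are grams.  Conversion from human units (nm, um, mL, mg/L, hours)
happens at the interface layers (:mod:`nanoperm.pipeline`, packaged data),
never here.

The model is quasi-steady: one algebraic evaluation of the steady Fick flux
per scenario, with the permeated mass accounting for donor depletion through
the finite chamber volume.  No transient profiles, no back-diffusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "K_B",
    "G",
    "ParticleSpec",
    "MediumSpec",
    "CellConditions",
    "TransportResult",
    "diffusion_coefficient",
    "sedimentation_velocity",
    "sedimentation_distance",
    "mass_flux",
    "effective_diffusivity_from_concentration",
    "acceptor_concentration_from_Def",
    "retardation_coefficient",
    "permeated_mass",
]

#: Boltzmann constant, J/K (CODATA 2018 exact value).
K_B = 1.380649e-23

#: Standard gravitational acceleration, m/s^2.
G = 9.81


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ParticleSpec:
    """A spherical nanoparticle.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"nanoAg"``.
    d : float
        Particle diameter, metres.
    rho_s : float
        Solid density of the particle material, kg/m^3.
    """

    name: str
    d: float
    rho_s: float

    def __post_init__(self) -> None:
        _require_positive(self.d, "d")
        _require_positive(self.rho_s, "rho_s")


@dataclass(frozen=True)
class MediumSpec:
    """The fluid phase through which particles diffuse.

    Parameters
    ----------
    T : float
        Absolute temperature, K.
    mu : float
        Dynamic viscosity, Pa*s.
    rho_c : float
        Fluid density, kg/m^3.
    """

    T: float
    mu: float
    rho_c: float

    def __post_init__(self) -> None:
        _require_positive(self.T, "T")
        _require_positive(self.mu, "mu")
        _require_positive(self.rho_c, "rho_c")


@dataclass(frozen=True)
class CellConditions:
    """Operating conditions of a diffusion (Franz-cell type) experiment.

    Parameters
    ----------
    A : float
        Exchange cross-section area, m^2.
    V : float
        Liquid volume per chamber, m^3.
    t : float
        Process duration, seconds.
    c0 : float
        Initial donor concentration, g/m^3 (numerically mg/L).
    """

    A: float
    V: float
    t: float
    c0: float

    def __post_init__(self) -> None:
        for field in ("A", "V", "t", "c0"):
            _require_positive(getattr(self, field), field)

    @property
    def m0(self) -> float:
        """Initial donor nanoparticle mass c0*V, grams."""
        return self.c0 * self.V


@dataclass(frozen=True)
class TransportResult:
    """Bundle of the transport quantities for one barrier scenario.

    Attributes
    ----------
    D : float
        Free-liquid Stokes-Einstein diffusivity, m^2/s.
    D_ef : float
        Effective diffusivity through the barrier, m^2/s.
    a : float
        Retardation coefficient D_ef/D, dimensionless.
    J : float
        Mass flux, g/(m^2*s).
    c_p : float
        Acceptor concentration after the run, g/m^3.
    m_p : float
        Permeated mass, grams.
    """

    D: float
    D_ef: float
    a: float
    J: float
    c_p: float
    m_p: float


def diffusion_coefficient(particle: ParticleSpec, medium: MediumSpec) -> float:
    """Stokes-Einstein diffusivity of a sphere, D = kB*T / (6*pi*mu*d).

    Returns m^2/s.  For a 9 nm particle in water at 20 C this is
    ~2.39e-11 m^2/s.
    """
    return K_B * medium.T / (6.0 * 3.141592653589793 * medium.mu * particle.d)


def sedimentation_velocity(particle: ParticleSpec, medium: MediumSpec) -> float:
    """Stokes terminal settling velocity u0 = d^2*g*(rho_s - rho_c) / (18*mu).

    Returns m/s.  Negative when the particle is buoyant (rho_s < rho_c).
    """
    return (
        particle.d**2 * G * (particle.rho_s - medium.rho_c) / (18.0 * medium.mu)
    )


def sedimentation_distance(u0: float, t: float) -> float:
    """Distance s = u0*t covered by a particle settling at velocity ``u0``."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t!r}")
    return u0 * t


def mass_flux(m_p: float, A: float, t: float) -> float:
    """Mass flux J = m_p / (A*t) in g/(m^2*s)."""
    _require_positive(A, "A")
    _require_positive(t, "t")
    if m_p < 0:
        raise ValueError(f"m_p must be non-negative, got {m_p!r}")
    return m_p / (A * t)


def effective_diffusivity_from_concentration(
    c_p: float, cond: CellConditions, L: float
) -> float:
    """Invert the steady Fick flux for the effective diffusivity.

    With the permeated mass read off the acceptor concentration,
    m_p = c_p*V, the steady flux J = D_ef*(c0 - c_p)/L gives

        D_ef = c_p*V*L / (A*t*(c0 - c_p)).

    This is the exact algebraic inverse of
    :func:`acceptor_concentration_from_Def`.

    Raises
    ------
    ValueError
        If ``c_p`` is negative, or if ``c_p >= c0`` (the steady-state
        premise c0 > c_p is violated and no finite diffusivity exists).
    """
    _require_positive(L, "L")
    if c_p < 0:
        raise ValueError(f"c_p must be non-negative, got {c_p!r}")
    if c_p >= cond.c0:
        raise ValueError(
            "steady-state assumption violated: acceptor concentration "
            f"c_p={c_p!r} must stay below the donor concentration c0={cond.c0!r}"
        )
    return c_p * cond.V * L / (cond.A * cond.t * (cond.c0 - c_p))


def acceptor_concentration_from_Def(
    D_ef: float, cond: CellConditions, L: float
) -> float:
    """Acceptor concentration predicted by the quasi-steady model.

    c_p = D_ef*A*t*c0 / (V*L + D_ef*A*t); always in [0, c0), approaching
    c0 only in the infinite-diffusivity limit.
    """
    _require_positive(L, "L")
    if D_ef < 0:
        raise ValueError(f"D_ef must be non-negative, got {D_ef!r}")
    At = cond.A * cond.t
    return D_ef * At * cond.c0 / (cond.V * L + D_ef * At)


def retardation_coefficient(D_ef: float, D: float) -> float:
    """Retardation a = D_ef / D, the fraction of free diffusion surviving.

    Values above 1 are physically suspect (the barrier cannot accelerate
    diffusion) but can arise from measurement noise; they trigger a
    warning rather than an error.
    """
    _require_positive(D, "D")
    if D_ef < 0:
        raise ValueError(f"D_ef must be non-negative, got {D_ef!r}")
    if D_ef > D:
        warnings.warn(
            f"D_ef={D_ef!r} exceeds the free-liquid D={D!r}; retardation "
            "a > 1 is physically suspect (measurement noise?)",
            stacklevel=2,
        )
    return D_ef / D


def permeated_mass(D_ef: float, cond: CellConditions, L: float) -> float:
    """Mass permeating a barrier of thickness L in the quasi-steady model.

        m_p = D_ef*c0 / (L/(A*t) + D_ef/V)

    Strictly increasing in D_ef, bounded above by the initial donor mass
    m0 = c0*V (reached only in the L -> 0 limit).
    """
    _require_positive(L, "L")
    if D_ef < 0:
        raise ValueError(f"D_ef must be non-negative, got {D_ef!r}")
    return D_ef * cond.c0 / (L / (cond.A * cond.t) + D_ef / cond.V)
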