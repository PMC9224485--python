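"""End-to-end forward prediction of nanoparticle permeation.

Chains the geometry, adsorption and transport pieces: a barrier (filter
stack or brick-wall skin) is reduced to its thickness L and surface
parameter Y; the retention law gives the retardation a = 1/(1+kY); the
Stokes-Einstein diffusivity D of the particle in the medium is scaled to
D_ef = a*D; and the quasi-steady flux balance yields the permeated mass,
acceptor concentration, and — swept over the number of skin layers — a
depth profile and a penetration limit.

For skin, the medium's viscosity is that of the intercellular cement:
it enters only through the Stokes-Einstein diffusivity, not through k.
Depth is discretized in whole brick layers of pitch x_k + x_c;
continuous-depth queries interpolate Y linearly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .adsorption import retention_fraction
from .geometry import (
    DEFAULT_REFERENCE_AREA,
    BrickGeometry,
    FilterStack,
    brick_layer_surface_parameter,
    stack_properties,
)
from .physics import (
    G,
    K_B,
    CellConditions,
    MediumSpec,
    ParticleSpec,
    TransportResult,
    acceptor_concentration_from_Def,
    diffusion_coefficient,
    mass_flux,
    permeated_mass,
)

__all__ = [
    "SkinScenario",
    "PenetrationProfile",
    "stratum_corneum_scenario",
    "profile",
    "penetration_limit",
    "membrane_prediction",
]

logger = logging.getLogger(__name__)

#: Default dimensionless-mass cut-off below which permeation is considered
#: not to occur.
DEFAULT_MASS_THRESHOLD = 0.005


@dataclass(frozen=True)
class SkinScenario:
    """A brick-wall skin permeation scenario.

    Bundles the barrier geometry, the particle, the intercellular-cement
    medium (its viscosity governs the Stokes-Einstein diffusivity), the
    exposure conditions, the adsorption constant ``k`` for the surface
    class, and the dimensionless mass threshold used for the penetration
    limit.
    """

    geometry: BrickGeometry
    particle: ParticleSpec
    medium: MediumSpec
    conditions: CellConditions
    k: float
    threshold: float = DEFAULT_MASS_THRESHOLD
    A_F: float = DEFAULT_REFERENCE_AREA

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k!r}")
        if not (0 < self.threshold <= 1):
            raise ValueError(
                f"threshold must lie in (0, 1], got {self.threshold!r}"
            )

    @property
    def layer_surface_parameter(self) -> float:
        """Y contributed by one brick layer."""
        return brick_layer_surface_parameter(self.geometry, self.A_F)

    def surface_parameter_at(self, L: float) -> float:
        """Continuous-depth Y(L) = L / (x_k + x_c) * Y_layer (linear in L)."""
        if L < 0:
            raise ValueError(f"L must be non-negative, got {L!r}")
        return L / self.geometry.layer_pitch * self.layer_surface_parameter

    def with_(self, **changes) -> "SkinScenario":
        """Copy with selected fields replaced (parameter sweeps)."""
        return replace(self, **changes)

    @classmethod
    def from_config(cls, source: Mapping | str | Path) -> "SkinScenario":
        """Build a scenario from a flat config mapping or YAML file.

        Keys carry their units explicitly; unknown keys are rejected:

        ``particle_name`` (optional), ``diameter_nm``,
        ``solid_density_kg_m3`` (optional, default 7874),
        ``temperature_k``, ``viscosity_pa_s``,
        ``fluid_density_kg_m3`` (optional, default 1000),
        ``cell_side_um``, ``cell_thickness_um``, ``cement_thickness_um``,
        ``area_cm2``, ``volume_cm3``, ``time_h``, ``c0_mg_per_l``,
        ``k``, ``threshold`` (optional, default 0.005).
        """
        if isinstance(source, (str, Path)):
            import yaml

            with open(source) as fh:
                source = yaml.safe_load(fh)
        if not isinstance(source, Mapping):
            raise TypeError("scenario config must be a mapping")
        required = {
            "diameter_nm",
            "temperature_k",
            "viscosity_pa_s",
            "cell_side_um",
            "cell_thickness_um",
            "cement_thickness_um",
            "area_cm2",
            "volume_cm3",
            "time_h",
            "c0_mg_per_l",
            "k",
        }
        optional = {
            "particle_name",
            "solid_density_kg_m3",
            "fluid_density_kg_m3",
            "threshold",
        }
        keys = set(source)
        unknown = keys - required - optional
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        missing = required - keys
        if missing:
            raise ValueError(f"missing scenario keys: {sorted(missing)}")
        cfg = dict(source)
        return cls(
            geometry=BrickGeometry(
                w=cfg["cell_side_um"] * 1e-6,
                x_k=cfg["cell_thickness_um"] * 1e-6,
                x_c=cfg["cement_thickness_um"] * 1e-6,
            ),
            particle=ParticleSpec(
                name=cfg.get("particle_name", "particle"),
                d=cfg["diameter_nm"] * 1e-9,
                rho_s=cfg.get("solid_density_kg_m3", 7874.0),
            ),
            medium=MediumSpec(
                T=cfg["temperature_k"],
                mu=cfg["viscosity_pa_s"],
                rho_c=cfg.get("fluid_density_kg_m3", 1000.0),
            ),
            conditions=CellConditions(
                A=cfg["area_cm2"] * 1e-4,
                V=cfg["volume_cm3"] * 1e-6,
                t=cfg["time_h"] * 3600.0,
                c0=cfg["c0_mg_per_l"],
            ),
            k=cfg["k"],
            threshold=cfg.get("threshold", DEFAULT_MASS_THRESHOLD),
        )


def stratum_corneum_scenario(
    *,
    d: float = 9e-9,
    mu: float = 1e-3,
    k: float = 0.3884,
    T: float = 293.15,
    threshold: float = DEFAULT_MASS_THRESHOLD,
) -> SkinScenario:
    """The reference stratum-corneum scenario.

    35 x 35 x 1 um bricks with 0.05 um cement; exposure from a 2 mm film
    of 10 g/L suspension over 1 cm^2 for 12 h.  ``d``, ``mu``, ``k`` and
    ``threshold`` are the usual sweep knobs (particle size, cement
    viscosity, surface affinity, cut-off).
    """
    return SkinScenario(
        geometry=BrickGeometry(w=35e-6, x_k=1e-6, x_c=0.05e-6),
        particle=ParticleSpec(name="particle", d=d, rho_s=7874.0),
        medium=MediumSpec(T=T, mu=mu, rho_c=1000.0),
        conditions=CellConditions(A=1e-4, V=0.2e-6, t=12 * 3600.0, c0=1e4),
        k=k,
        threshold=threshold,
    )


@dataclass(frozen=True)
class PenetrationProfile:
    """Per-layer depth profile of permeation through brick-wall skin.

    ``table`` has one row per layer count N with columns
    N, L_m, Y, a, D_ef, m_p, m_ratio; ``m_ratio`` = m_p / (c0*V) is
    non-increasing in N.
    """

    scenario: SkinScenario
    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        """Write the profile with explicit units in the header and six
        significant digits per float."""
        out = pd.DataFrame(
            {
                "N": self.table["N"],
                "L_um": self.table["L_m"] * 1e6,
                "Y": self.table["Y"],
                "a": self.table["a"],
                "D_ef_m2_s": self.table["D_ef"],
                "m_p_g": self.table["m_p"],
                "m_ratio": self.table["m_ratio"],
            }
        )
        out.to_csv(path, index=False, float_format="%.6g")


def _sweep(scenario: SkinScenario, N: np.ndarray) -> pd.DataFrame:
    """Evaluate the forward chain for an array of layer counts."""
    cond = scenario.conditions
    D = diffusion_coefficient(scenario.particle, scenario.medium)
    L = N * scenario.geometry.layer_pitch
    Y = N * scenario.layer_surface_parameter
    a = retention_fraction(Y, scenario.k)
    D_ef = a * D
    m_p = D_ef * cond.c0 / (L / (cond.A * cond.t) + D_ef / cond.V)
    return pd.DataFrame(
        {
            "N": N,
            "L_m": L,
            "Y": Y,
            "a": a,
            "D_ef": D_ef,
            "m_p": m_p,
            "m_ratio": m_p / cond.m0,
        }
    )


def _log_scenario(scenario: SkinScenario, what: str) -> None:
    cond = scenario.conditions
    logger.info(
        "%s: d=%.3e m, T=%.2f K, mu=%.3e Pa.s, k=%.4f, Y_layer=%.4f, "
        "pitch=%.3e m, A=%.3e m2, V=%.3e m3, t=%.0f s, c0=%.1f g/m3, "
        "threshold=%.4g (constants: k_B=%.6e J/K, g=%.2f m/s2)",
        what,
        scenario.particle.d,
        scenario.medium.T,
        scenario.medium.mu,
        scenario.k,
        scenario.layer_surface_parameter,
        scenario.geometry.layer_pitch,
        cond.A,
        cond.V,
        cond.t,
        cond.c0,
        scenario.threshold,
        K_B,
        G,
    )


def profile(scenario: SkinScenario, N_max: int) -> PenetrationProfile:
    """Depth profile over N = 1..N_max brick layers.

    For each N: L = N*(x_k+x_c), Y = N*Y_layer, a = 1/(1+kY),
    D_ef = a*D, and the permeated mass from the quasi-steady flux balance.
    """
    if N_max < 1:
        raise ValueError(f"N_max must be >= 1, got {N_max!r}")
    _log_scenario(scenario, "profile")
    N = np.arange(1, N_max + 1)
    return PenetrationProfile(scenario=scenario, table=_sweep(scenario, N))


def penetration_limit(scenario: SkinScenario, N_max: int = 10**6) -> int:
    """Largest layer count whose dimensionless permeated mass still meets
    the scenario threshold.

    m_ratio(N) decreases monotonically in N, so an ascending scan stops at
    the first layer falling below the threshold; returns 0 when even a
    single layer is below it.
    """
    _log_scenario(scenario, "penetration_limit")
    chunk = 4096
    start = 1
    while start <= N_max:
        stop = min(start + chunk - 1, N_max)
        N = np.arange(start, stop + 1)
        ratio = _sweep(scenario, N)["m_ratio"].to_numpy()
        below = np.nonzero(ratio < scenario.threshold)[0]
        if below.size:
            return int(N[below[0]]) - 1
        start = stop + 1
    raise RuntimeError(
        f"penetration limit not reached within N_max={N_max} layers"
    )


def membrane_prediction(
    stack: FilterStack,
    particle: ParticleSpec,
    medium: MediumSpec,
    cond: CellConditions,
    k: float,
) -> TransportResult:
    """Forward prediction of transport through a woven filter stack.

    Chains stack geometry -> retention law -> effective diffusivity ->
    permeated mass / acceptor concentration, returning the full
    transport bundle.
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k!r}")
    L, Y = stack_properties(stack)
    D = diffusion_coefficient(particle, medium)
    a = retention_fraction(Y, k)
    D_ef = a * D
    m_p = permeated_mass(D_ef, cond, L)
    return TransportResult(
        D=D,
        D_ef=D_ef,
        a=a,
        J=mass_flux(m_p, cond.A, cond.t),
        c_p=acceptor_concentration_from_Def(D_ef, cond, L),
        m_p=m_p,
    )
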