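"""Packaged reference data: the filter library and the measured retention table.

The filter library holds the four commercially woven polyacrylamide meshes
(three hydrophilic, one surface-modified hydrophobic) with their measured
mesh size, thread diameter and single-layer thickness.  The retention table
holds the measured effective diffusivities and retardation coefficients for
silver and copper nanoparticles diffusing through twelve single- and
multi-layer filter configurations in a Franz cell, together with each
configuration's total thickness and surface parameter Y.

These tables are small, static inputs; they are shipped as CSV inside the
package so every downstream computation (retardation, adsorption fit,
forward prediction) can run without external files.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .adsorption import RetentionObservation
from .geometry import FilterStack, MeshFilterSpec, Wettability
from .physics import CellConditions, MediumSpec, ParticleSpec

__all__ = [
    "load_filters",
    "load_retention_table",
    "retention_observations",
    "stack_from_label",
    "nano_silver",
    "nano_copper",
    "water",
    "franz_cell_conditions",
    "K_HYDROPHILIC",
    "K_HYDROPHOBIC",
]

#: Adsorption model constants fitted to the measured retention data
#: (see :func:`nanoperm.adsorption.fit_model_constant`), one per
#: wettability class.
K_HYDROPHILIC = 0.3884
K_HYDROPHOBIC = 1.6016


def _data_file(name: str):
    return resources.files("nanoperm.data").joinpath(name)


def load_filters() -> dict[str, MeshFilterSpec]:
    """The packaged filter library, keyed by label (F118, F63, F1, F9*)."""
    with resources.as_file(_data_file("filters.csv")) as path:
        table = pd.read_csv(path)
    filters: dict[str, MeshFilterSpec] = {}
    for row in table.itertuples(index=False):
        filters[row.label] = MeshFilterSpec(
            label=row.label,
            wettability=Wettability.parse(row.wettability),
            l_h=row.mesh_size_um * 1e-6,
            d_f=row.thread_diameter_um * 1e-6,
            thickness=row.thickness_um * 1e-6,
        )
    return filters


def load_retention_table() -> pd.DataFrame:
    """The measured retention data, one row per (configuration, particle).

    Columns: config, group (HI / HF / mixed), L_um, Y, particle,
    D_ef_m2_s, a.  The two mixed-wettability stacks belong to neither
    fit group and are excluded from the per-class adsorption fits.
    """
    with resources.as_file(_data_file("retention.csv")) as path:
        return pd.read_csv(path)


def retention_observations(group: str | None = None) -> list[RetentionObservation]:
    """Measured (Y, a) observations, optionally restricted to one group.

    ``group`` is ``"HI"`` (hydrophilic), ``"HF"`` (hydrophobic),
    ``"mixed"``, or None for all observations.
    """
    table = load_retention_table()
    if group is not None:
        if group not in {"HI", "HF", "mixed"}:
            raise ValueError(f"unknown group {group!r}")
        table = table[table["group"] == group]
    group_names = {"HI": "hydrophilic", "HF": "hydrophobic", "mixed": "mixed"}
    return [
        RetentionObservation(
            Y=row.Y,
            a=row.a,
            group=group_names[row.group],
            particle_label=row.particle,
        )
        for row in table.itertuples(index=False)
    ]


def stack_from_label(label: str) -> FilterStack:
    """Build a filter stack from a '+'-joined label, e.g. ``"F118+F63"``."""
    filters = load_filters()
    try:
        layers = [filters[part.strip()] for part in label.split("+")]
    except KeyError as exc:
        raise ValueError(f"unknown filter {exc.args[0]!r} in {label!r}") from None
    return FilterStack(layers)


def nano_silver() -> ParticleSpec:
    """9 nm silver nanoparticles (solid density as used in the retention
    measurements)."""
    return ParticleSpec(name="nanoAg", d=9e-9, rho_s=7874.0)


def nano_copper() -> ParticleSpec:
    """12 nm copper nanoparticles."""
    return ParticleSpec(name="nanoCu", d=12e-9, rho_s=8950.0)


def water(T: float = 293.15) -> MediumSpec:
    """Water at the measurement temperature (20 C by default)."""
    return MediumSpec(T=T, mu=1e-3, rho_c=1000.0)


def franz_cell_conditions() -> CellConditions:
    """The membrane-experiment operating point: 2 cm diameter exchange
    window (A = 3.14e-4 m^2), 10 mL per chamber, 12 h run, 400 mg/L
    donor concentration."""
    return CellConditions(A=3.14e-4, V=1e-5, t=12 * 3600.0, c0=400.0)
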