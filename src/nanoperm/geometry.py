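"""Barrier geometry: the dimensionless surface parameter Y and thickness L.

Y is the ratio of the total solid surface available for particle deposition
(thread mantles of a woven mesh, or all faces of the corneocyte "bricks")
to the reference barrier cross-section area A_F.  It is the single
geometric descriptor the adsorption-retention law consumes, and it is
independent of the choice of A_F because both areas scale together.

Two barrier families are covered:

* woven mesh filters, where threads are counted from the mesh size and
  thread diameter, with an alternating double-splice weave in one
  direction (triplets of width 3*d_f + 2*l_h) and a plain weave in the
  other;
* the brick-wall idealization of the stratum corneum, cuboidal cells of
  side ``w`` and thickness ``x_k`` separated by intercellular cement of
  thickness ``x_c``.

Thread/brick counts are real-valued by default; integer rounding is an
explicit option retained only for cross-checking hand counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

__all__ = [
    "Wettability",
    "MeshFilterSpec",
    "FilterStack",
    "BrickGeometry",
    "thread_counts",
    "mesh_surface_parameter",
    "stack_properties",
    "brick_total_area",
    "bricks_per_layer",
    "brick_layer_surface_parameter",
    "DEFAULT_REFERENCE_AREA",
]

#: Default reference area A_F: a 1 cm x 1 cm square, in m^2.
DEFAULT_REFERENCE_AREA = 1e-4


class Wettability(str, Enum):
    """Surface wettability class of a filter; each class has its own
    adsorption model constant k."""

    HYDROPHILIC = "hydrophilic"
    HYDROPHOBIC = "hydrophobic"

    @classmethod
    def parse(cls, text: str) -> "Wettability":
        """Accept the long names or the HI/HF shorthand."""
        key = text.strip().lower()
        aliases = {
            "hi": cls.HYDROPHILIC,
            "hf": cls.HYDROPHOBIC,
            "hydrophilic": cls.HYDROPHILIC,
            "hydrophobic": cls.HYDROPHOBIC,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown wettability {text!r}") from None


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class MeshFilterSpec:
    """One woven mesh filter layer.

    Parameters
    ----------
    label : str
        Short identifier, e.g. ``"F118"``.
    wettability : Wettability
    l_h : float
        Mesh (opening) size, metres.
    d_f : float
        Thread diameter, metres.
    thickness : float
        Single-layer thickness, metres.
    """

    label: str
    wettability: Wettability
    l_h: float
    d_f: float
    thickness: float

    def __post_init__(self) -> None:
        _require_positive(self.l_h, "l_h")
        _require_positive(self.d_f, "d_f")
        _require_positive(self.thickness, "thickness")


@dataclass(frozen=True)
class FilterStack:
    """An ordered stack of mesh filter layers; thickness and Y add."""

    layers: tuple[MeshFilterSpec, ...]

    def __init__(self, layers: Sequence[MeshFilterSpec]):
        if len(layers) == 0:
            raise ValueError("a filter stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(layers))

    @property
    def label(self) -> str:
        return "+".join(f.label for f in self.layers)


@dataclass(frozen=True)
class BrickGeometry:
    """Brick-wall stratum-corneum geometry.

    Square bricks of side ``w`` and thickness (depth dimension) ``x_k``,
    separated laterally and between layers by cement gaps of thickness
    ``x_c``; the layer pitch is ``x_k + x_c``.  All lengths in metres.
    """

    w: float
    x_k: float
    x_c: float

    def __post_init__(self) -> None:
        _require_positive(self.w, "w")
        _require_positive(self.x_k, "x_k")
        _require_positive(self.x_c, "x_c")

    @property
    def layer_pitch(self) -> float:
        """Depth occupied by one layer of bricks plus its cement gap, m."""
        return self.x_k + self.x_c


def thread_counts(
    filter: MeshFilterSpec, h: float = 1e-2, rounded: bool = False
) -> tuple[float, float]:
    """Thread counts (n_x, n_y) across a square reference region of side h.

    In the plain direction threads repeat every ``d_f + l_h``:
    n_x = h / (d_f + l_h).  In the double-splice direction every other
    splice carries a doubled thread, so three threads span
    ``3*d_f + 2*l_h``: n_y = 3*h / (3*d_f + 2*l_h).

    Counts are real-valued by default.  ``rounded=True`` reproduces the
    hand-count convention (for cross-checking tallies only — surface
    parameters always use the unrounded values): plain-direction threads
    are rounded to the nearest integer, while in the double-splice
    direction only whole threads of the final triplet are counted, i.e.
    the count is truncated.
    """
    _require_positive(h, "h")
    n_x = h / (filter.d_f + filter.l_h)
    n_y = 3.0 * h / (3.0 * filter.d_f + 2.0 * filter.l_h)
    if rounded:
        return float(round(n_x)), float(math.floor(n_y + 1e-9))
    return n_x, n_y


def mesh_surface_parameter(
    filter: MeshFilterSpec, A_F: float = DEFAULT_REFERENCE_AREA
) -> float:
    """Surface parameter Y of one mesh layer over reference area A_F.

    Threads are modelled as full cylinders of length h = sqrt(A_F) with
    no subtraction of crossing overlaps, so the total thread area is
    A_N = (n_x + n_y) * pi * d_f * h and Y = A_N / A_F.  Y is invariant
    to the choice of A_F (both counts scale with h).
    """
    _require_positive(A_F, "A_F")
    h = math.sqrt(A_F)
    n_x, n_y = thread_counts(filter, h)
    return (n_x + n_y) * math.pi * filter.d_f * h / A_F


def stack_properties(stack: FilterStack) -> tuple[float, float]:
    """Total thickness L (m) and surface parameter Y of a filter stack.

    Both quantities are additive over layers.
    """
    L = sum(f.thickness for f in stack.layers)
    Y = sum(mesh_surface_parameter(f) for f in stack.layers)
    return L, Y


def brick_total_area(g: BrickGeometry) -> float:
    """Total surface area of one brick (all six faces), m^2.

    A_S = 2*w^2 + 4*w*x_k for a square brick of side w and thickness x_k.
    """
    return 2.0 * g.w**2 + 4.0 * g.w * g.x_k


def bricks_per_layer(
    g: BrickGeometry, A_F: float = DEFAULT_REFERENCE_AREA, rounded: bool = False
) -> float:
    """Number of bricks in one layer over a square reference area A_F.

    Bricks repeat laterally every ``w + x_c``, so a side h = sqrt(A_F)
    holds n_d = h/(w + x_c) bricks and the layer holds n = n_d^2.  The
    count is real-valued by default.
    """
    _require_positive(A_F, "A_F")
    h = math.sqrt(A_F)
    n_d = h / (g.w + g.x_c)
    if rounded:
        n_d = round(n_d)
    return float(n_d) ** 2


def brick_layer_surface_parameter(
    g: BrickGeometry, A_F: float = DEFAULT_REFERENCE_AREA
) -> float:
    """Surface parameter of a single brick layer: Y = n * A_S / A_F.

    For the default stratum-corneum geometry (35 um bricks, 1 um thick,
    0.05 um cement) this is ~2.108 per layer; Y for N layers is
    N times this value (additivity over layers).
    """
    return bricks_per_layer(g, A_F) * brick_total_area(g) / A_F
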