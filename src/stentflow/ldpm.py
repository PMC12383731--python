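"""Local-density porous model: cell-wise screen resistance for braided stents.

A braided flow diverter acts on through-flow like a woven screen.  The
pressure loss across one braid cell of porosity ``eps`` and hydraulic
diameter ``D_h`` follows the screen correlation

    dp = -(rho/2) * [1.3(1-eps) + (1/eps - 1)^2] * v^2  -  11 mu v / D_h

with ``v`` the through-screen (shell-normal) velocity.  The stent shell is a
hollow cylinder of thickness twice the wire diameter; each solver cell
inside it inherits the coefficients of the geometrically nearest braid cell,
so the momentum sink varies with the local wire density that deployment
produced.  The jump ``dp`` is converted to a per-volume sink by dividing by
the resolved shell thickness, which keeps the integrated pressure jump
independent of how many grid layers span the shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FluidProperties",
    "PorousField",
    "CoilFill",
    "porosity",
    "hydraulic_diameter",
    "inertial_bracket",
    "pressure_loss",
    "build_porous_field",
    "build_coil_region",
]


class PorousModelError(ValueError):
    pass


@dataclass
class FluidProperties:
    """Blood-like fluid: density and a (pluggable) viscosity law.

    ``viscosity_law`` maps shear rate (1/s) to dynamic viscosity (Pa s);
    the default is Newtonian at 3.6 mPa s, a standard whole-blood value.
    """

    density: float = 1100.0
    viscosity: float = 3.6e-3
    viscosity_law: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise PorousModelError("density and viscosity must be positive")

    def mu(self, shear_rate: float | np.ndarray = 0.0) -> np.ndarray | float:
        if self.viscosity_law is None:
            return self.viscosity
        out = self.viscosity_law(np.asarray(shear_rate, dtype=float))
        if np.any(np.asarray(out) <= 0):
            raise PorousModelError("viscosity law returned a non-positive value")
        return out


def porosity(A_t: float, A_w: float) -> float:
    """Cell porosity eps = A_p/A_t = (A_t - A_w)/A_t."""
    if A_t <= 0:
        raise PorousModelError("total cell area must be positive")
    if A_w < 0 or A_w > A_t:
        raise PorousModelError("wire area must satisfy 0 <= A_w <= A_t")
    return (A_t - A_w) / A_t


def hydraulic_diameter(
    side_length: float,
    alpha: float,
    mode: str = "verbatim",
    wire_diameter: float = 0.0,
) -> float:
    """Pore length scale of a rhombic braid cell.

    mode='verbatim' returns ``side_length * sin(alpha)`` (the correlation's
    printed form, reading its symbol as the rhombus side).  mode=
    'pore_hydraulic' returns 4*A_p/P_p of the open rhombic pore whose side is
    ``side_length - d_w/sin(alpha)``, which equals that pore side times
    sin(alpha); the two modes coincide as the wire diameter goes to zero.
    """
    if side_length <= 0:
        raise PorousModelError("side length must be positive")
    if not (1e-6 < alpha < np.pi - 1e-6):
        raise PorousModelError("degenerate cell: braid angle at 0 or pi")
    sin_a = np.sin(alpha)
    if mode == "verbatim":
        return side_length * sin_a
    if mode == "pore_hydraulic":
        s_p = side_length - wire_diameter / sin_a
        if s_p <= 0:
            raise PorousModelError("pore fully occluded by wires")
        return s_p * sin_a
    raise PorousModelError(f"unknown hydraulic-diameter mode {mode!r}")


def inertial_bracket(eps: np.ndarray | float) -> np.ndarray | float:
    """The screen inertial-loss factor 1.3(1-eps) + (1/eps - 1)^2.

    Strictly decreasing in eps on (0, 1]; zero at eps = 1.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps > 1):
        raise PorousModelError("porosity must lie in (0, 1]")
    out = 1.3 * (1.0 - eps) + (1.0 / eps - 1.0) ** 2
    return float(out) if out.ndim == 0 else out


def pressure_loss(
    eps: float, D_h: float, v: float, fluid: FluidProperties, shear_rate: float = 0.0
) -> float:
    """Screen pressure loss (Pa) at through-screen speed ``v``.

    Negative values are losses along the flow direction; the quadratic term
    uses |v|*v so the loss always opposes the through-flow.
    """
    if eps <= 0:
        raise PorousModelError("eps = 0: fully occluded cell, treat as solid wall")
    if eps > 1:
        raise PorousModelError("porosity cannot exceed 1")
    if D_h <= 0:
        raise PorousModelError("hydraulic diameter must be positive")
    mu = float(np.asarray(fluid.mu(shear_rate)))
    return float(
        -(fluid.density / 2.0) * inertial_bracket(eps) * abs(v) * v - 11.0 * mu * v / D_h
    )


@dataclass
class PorousField:
    """Per-grid-cell momentum-sink coefficients.

    Shell (normal-directed screen) part: ``C2`` multiplies |v_n| v_n and
    ``C1`` multiplies v_n; both are divided by the per-cell resolved layer
    thickness ``t_eff`` to give a per-volume sink opposing the shell-normal
    velocity component.  Coil part: isotropic per-volume Darcy-Forchheimer
    coefficients ``C1_iso`` (Pa s/m^2) and ``C2_iso`` (kg/m^4).
    """

    shape: tuple[int, ...]
    C1: np.ndarray = field(default=None)            # type: ignore[assignment]
    C2: np.ndarray = field(default=None)            # type: ignore[assignment]
    normal: np.ndarray = field(default=None)        # type: ignore[assignment]
    t_eff: np.ndarray = field(default=None)         # type: ignore[assignment]
    C1_iso: np.ndarray = field(default=None)        # type: ignore[assignment]
    C2_iso: np.ndarray = field(default=None)        # type: ignore[assignment]
    region_tag: np.ndarray = field(default=None)    # type: ignore[assignment]
    cell_index: np.ndarray = field(default=None)    # stent cell feeding each grid cell

    TAG_NONE, TAG_SHELL, TAG_COIL = 0, 1, 2

    def __post_init__(self) -> None:
        sh = self.shape
        z = lambda: np.zeros(sh)  # noqa: E731
        if self.C1 is None:
            self.C1 = z()
        if self.C2 is None:
            self.C2 = z()
        if self.normal is None:
            self.normal = np.zeros(sh + (2,))
        if self.t_eff is None:
            self.t_eff = np.ones(sh)
        if self.C1_iso is None:
            self.C1_iso = z()
        if self.C2_iso is None:
            self.C2_iso = z()
        if self.region_tag is None:
            self.region_tag = np.zeros(sh, dtype=np.int8)
        if self.cell_index is None:
            self.cell_index = np.full(sh, -1, dtype=np.int64)
        if np.any(self.C1 < 0) or np.any(self.C2 < 0):
            raise PorousModelError("porous coefficients must be nonnegative")

    @classmethod
    def empty(cls, shape: tuple[int, ...]) -> "PorousField":
        return cls(shape=shape)

    def is_empty(self) -> bool:
        return not (
            np.any(self.C1) or np.any(self.C2) or np.any(self.C1_iso) or np.any(self.C2_iso)
        )

    def add(self, other: "PorousField") -> "PorousField":
        """Superpose another contribution (e.g. the coil region)."""
        if other.shape != self.shape:
            raise PorousModelError("porous field shapes do not match")
        out = PorousField(
            shape=self.shape,
            C1=self.C1 + other.C1,
            C2=self.C2 + other.C2,
            normal=np.where(
                (np.abs(other.normal).sum(-1) > 0)[..., None], other.normal, self.normal
            ),
            t_eff=np.where(other.C1 + other.C2 > 0, other.t_eff, self.t_eff),
            C1_iso=self.C1_iso + other.C1_iso,
            C2_iso=self.C2_iso + other.C2_iso,
            region_tag=np.maximum(self.region_tag, other.region_tag),
            cell_index=np.where(other.cell_index >= 0, other.cell_index, self.cell_index),
        )
        return out


def shell_coefficients(cells: Sequence, fluid: FluidProperties) -> np.ndarray:
    """Per-braid-cell (C1, C2): C1 = 11 mu / D_h, C2 = (rho/2)*bracket(eps)."""
    eps = np.array([c.porosity for c in cells])
    dh = np.array([c.hydraulic_diameter for c in cells])
    if np.any(eps <= 0):
        raise PorousModelError("fully occluded braid cell: treat as solid")
    mu = float(np.asarray(fluid.mu(0.0)))
    c1 = 11.0 * mu / dh
    c2 = (fluid.density / 2.0) * np.asarray(inertial_bracket(eps))
    return np.column_stack([c1, c2])


def build_porous_field(
    cells: Sequence,
    grid,
    t_shell: float,
    fluid: FluidProperties,
    intersections_zero: bool = False,
    crossing_points: np.ndarray | None = None,
    wire_diameter: float = 30e-6,
) -> PorousField:
    """Assemble the shell momentum-sink field on a solver grid.

    ``grid`` must expose ``shape``, boolean ``shell_mask``, per-shell-cell
    surface coordinates ``shell_coords`` (arc position s, circumferential
    angle theta, local surface radius) and ``shell_normal`` (unit 2-vector
    per shell cell in grid coordinates) plus ``shell_teff`` (resolved layer
    thickness per shell cell).  Each shell cell inherits the coefficients of
    the stent cell with the nearest centroid in (s, theta)-surface metric;
    nearest lookup is a KD-tree on (s, R cos theta, R sin theta).

    With ``intersections_zero`` the resistance is zeroed for grid cells
    mapping within one wire diameter of a wire crossing (off by default).
    """
    if len(cells) == 0:
        raise PorousModelError("no stent cells supplied")
    field_ = PorousField.empty(tuple(grid.shape))
    mask = np.asarray(grid.shell_mask, dtype=bool)
    if not mask.any():
        raise PorousModelError(
            "no grid cells intersect the stent shell: refine the grid so at "
            "least one layer conforms to the shell region"
        )
    coords = np.asarray(grid.shell_coords, dtype=float)  # (n_shell, 3): s, theta, R
    coeff = shell_coefficients(cells, fluid)
    s_c = np.array([c.arc_position for c in cells])
    th_c = np.array([c.angle for c in cells])
    Rbar = float(np.mean(coords[:, 2])) if len(coords) else 1.0
    tree = cKDTree(
        np.column_stack([s_c, Rbar * np.cos(th_c), Rbar * np.sin(th_c)])
    )
    q = np.column_stack(
        [coords[:, 0], Rbar * np.cos(coords[:, 1]), Rbar * np.sin(coords[:, 1])]
    )
    _, nearest = tree.query(q)
    c1 = coeff[nearest, 0]
    c2 = coeff[nearest, 1]
    if intersections_zero and crossing_points is not None and len(crossing_points):
        xp = np.asarray(crossing_points, dtype=float)
        xtree = cKDTree(
            np.column_stack(
                [xp[:, 0], Rbar * np.cos(xp[:, 1]), Rbar * np.sin(xp[:, 1])]
            )
        )
        d, _ = xtree.query(q)
        hit = d < wire_diameter
        c1 = np.where(hit, 0.0, c1)
        c2 = np.where(hit, 0.0, c2)
    idx = np.nonzero(mask)
    field_.C1[idx] = c1
    field_.C2[idx] = c2
    field_.normal[idx] = np.asarray(grid.shell_normal, dtype=float)
    field_.t_eff[idx] = np.asarray(grid.shell_teff, dtype=float)
    field_.region_tag[idx] = PorousField.TAG_SHELL
    field_.cell_index[idx] = nearest
    return field_


@dataclass(frozen=True)
class CoilFill:
    """Coil packing of the aneurysm sac.

    ``ver`` is the volume embolization ratio: total coil volume over
    aneurysm volume.  ``coil_wire_diameter`` is the primary wire diameter of
    the coil (m), the characteristic grain size of the packed region.
    """

    coil_wire_diameter: float = 0.25e-3
    coil_length: float = 0.20
    ver: float = 0.012

    def __post_init__(self) -> None:
        if not (0 <= self.ver < 1):
            raise PorousModelError("need 0 <= VER < 1")
        if self.coil_wire_diameter <= 0:
            raise PorousModelError("coil wire diameter must be positive")

    @classmethod
    def from_coils(
        cls, n_coils: int, sac_volume: float, coil_wire_diameter: float = 0.25e-3,
        coil_length: float = 0.20,
    ) -> "CoilFill":
        """VER from a coil count: n * (pi/4) d^2 L / V_sac."""
        vol = n_coils * np.pi * (coil_wire_diameter / 2) ** 2 * coil_length
        return cls(coil_wire_diameter, coil_length, float(vol / sac_volume))


def build_coil_region(
    spec: CoilFill, sac_mask: np.ndarray, fluid: FluidProperties
) -> PorousField:
    """Isotropic Darcy-Forchheimer sink over the coiled sac.

    The packed-coil region has solid fraction VER and porosity
    phi = 1 - VER.  Permeability follows the Kozeny-Carman relation with the
    coil wire diameter d_c as grain size, k = phi^3 d_c^2 / (180 (1-phi)^2),
    and the inertial coefficient follows the Ergun form
    1.75 rho (1-phi) / (d_c phi^3).  This is a documented stand-in for
    bespoke coil-resistance correlations.
    """
    sac_mask = np.asarray(sac_mask, dtype=bool)
    out = PorousField.empty(tuple(sac_mask.shape))
    if spec.ver == 0:
        return out
    phi = 1.0 - spec.ver
    d_c = spec.coil_wire_diameter
    k = phi**3 * d_c**2 / (180.0 * (1.0 - phi) ** 2)
    mu = float(np.asarray(fluid.mu(0.0)))
    out.C1_iso[sac_mask] = mu / k
    out.C2_iso[sac_mask] = 1.75 * fluid.density * (1.0 - phi) / (d_c * phi**3)
    out.region_tag[sac_mask] = PorousField.TAG_COIL
    return out
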