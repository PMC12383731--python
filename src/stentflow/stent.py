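"""Simplified virtual deployment of a braided flow-diverter stent.

The device is modelled as two counter-rotating families of inextensible
helical wires lying on the lumen wall.  Radial constraint scissors the
braid: with the between-wire angle ``alpha`` measured at the axial vertex of
each rhombus cell, the circumferential diagonal of a cell is
``2*s_cell*sin(alpha/2)`` and ``n_wires/2`` cells tile the circumference, so
wire inextensibility (fixed cell side ``s_cell``) gives

    sin(alpha_local/2) / R_local = sin(alpha_0/2) / R_nominal

clipped to alpha in (0.05*pi, 0.95*pi).  A vessel narrower than nominal
therefore lowers ``alpha`` — wires turn axial, the stent elongates, and cells
open up (the classical oversizing effect on metal coverage).

Wires advance by equal wire-length steps; on curved vessels the mapping onto
the bent tube packs crossings physically closer on the inner curve and
spreads them on the outer curve, which is exactly the local-density
heterogeneity the porous model downstream is built to carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselGeometry
from .ldpm import hydraulic_diameter, porosity

__all__ = ["StentDesign", "DeployedStent", "StentCell", "deploy_stent", "extract_cells"]


class DeploymentError(ValueError):
    pass


@dataclass(frozen=True)
class StentDesign:
    """Braided-stent design parameters.

    ``nominal_braid_angle`` is the between-wire angle at the axial vertex of
    a braid cell when the device is fully expanded to its nominal diameter;
    flow diverters braid their wires nearly circumferentially, so the default
    is 150 degrees.  ``shell_thickness`` is the radial extent of the wire
    region, twice the wire diameter (wires overlap at crossings).
    """

    n_wires: int = 48
    wire_diameter: float = 30e-6
    nominal_diameter: float = 4.5e-3
    nominal_length: float = 20e-3
    nominal_braid_angle: float = np.deg2rad(150.0)
    shell_thickness: float | None = None

    def __post_init__(self) -> None:
        if self.n_wires % 2 or not (4 <= self.n_wires <= 200):
            raise DeploymentError("n_wires must be even (48-96 for clinical devices)")
        if self.wire_diameter <= 0 or self.nominal_diameter <= 0 or self.nominal_length <= 0:
            raise DeploymentError("dimensions must be positive")
        if not (0 < self.nominal_braid_angle < np.pi):
            raise DeploymentError("braid angle must lie in (0, pi)")
        if self.shell_thickness is None:
            object.__setattr__(self, "shell_thickness", 2 * self.wire_diameter)

    @property
    def wire_free_length(self) -> float:
        """Length of one wire, fixed by the nominal configuration."""
        return self.nominal_length / np.cos(self.nominal_braid_angle / 2)


_ALPHA_LO, _ALPHA_HI = 0.05 * np.pi, 0.95 * np.pi


def local_braid_angle(design: StentDesign, local_radius: np.ndarray) -> np.ndarray:
    """Between-wire angle when the braid is constrained to ``local_radius``."""
    s = np.sin(design.nominal_braid_angle / 2) * (
        np.asarray(local_radius, dtype=float) / (design.nominal_diameter / 2)
    )
    half = np.arcsin(np.clip(s, np.sin(_ALPHA_LO / 2), np.sin(_ALPHA_HI / 2)))
    return 2 * half


@dataclass
class DeployedStent:
    """Result of a virtual deployment.

    ``s_dense``/``theta_rate`` tabulate the common winding of all wires as a
    function of arc position; each wire of the two families is the curve
    ``theta_i(s) = theta_i0 +/- Theta(s)`` mapped onto the lumen surface.
    """

    design: StentDesign
    vessel: VesselGeometry
    start: float
    end: float
    s_dense: np.ndarray          # arc positions, start..end
    Theta: np.ndarray            # cumulative winding angle at s_dense
    wire_length: np.ndarray      # cumulative wire length at s_dense
    alpha: np.ndarray            # local braid angle at s_dense
    wire_paths: list[np.ndarray] = field(default_factory=list)
    poor_apposition: bool = False

    @property
    def coverage_span(self) -> tuple[float, float]:
        return (self.start, self.end)

    def local_radius(self, s):
        return self.vessel.radius_at(s)

    def deployed_wire_lengths(self) -> np.ndarray:
        """Polyline length of every wire path (m)."""
        return np.array(
            [np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) for p in self.wire_paths]
        )


def _dense_frames(vessel: VesselGeometry, s: np.ndarray):
    """Vectorized interpolated frames at arc positions ``s``."""
    sl = vessel.arc_length
    p = np.column_stack([np.interp(s, sl, vessel.points[:, k]) for k in range(3)])
    t = np.column_stack([np.interp(s, sl, vessel.tangents[:, k]) for k in range(3)])
    n = np.column_stack([np.interp(s, sl, vessel.normals[:, k]) for k in range(3)])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n -= t * np.sum(n * t, axis=1, keepdims=True)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    b = np.cross(t, n)
    return p, t, n, b


def _surface_points(vessel: VesselGeometry, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
    p, _t, n, b = _dense_frames(vessel, s)
    r = vessel.radius_at(s)[:, None]
    return p + r * (np.cos(theta)[:, None] * n + np.sin(theta)[:, None] * b)


def deploy_stent(
    design: StentDesign,
    vessel: VesselGeometry,
    start_position: float = 0.0,
    samples_per_ring: int = 8,
) -> DeployedStent:
    """Deploy the braid along the vessel starting at ``start_position``.

    Each wire is advanced in equal wire-length steps with the local braid
    angle set by the radial constraint; deployment stops when the design
    free length of the wires is consumed.  Raises if the vessel is too short
    for the deployed (possibly elongated) stent; flags poor wall apposition
    when the lumen exceeds the nominal diameter by more than 20%.
    """
    R0 = design.nominal_diameter / 2
    # integrate ds = cos(alpha/2) dl on a dense arc grid from the start
    span = vessel.length - start_position
    if span <= 0:
        raise DeploymentError("start_position beyond the end of the vessel")
    m = max(2000, 50 * int(design.nominal_length / max(span, 1e-9) * 100))
    s_grid = np.linspace(start_position, vessel.length, m)
    R = vessel.radius_at(s_grid)
    if np.any(R > 1.2 * R0):
        poor = True
    else:
        poor = False
    alpha = local_braid_angle(design, R)
    half = alpha / 2
    # wire length per unit arc and winding rate per unit arc
    dl_ds = 1.0 / np.cos(half)
    dTheta_ds = np.tan(half) / R
    ds = np.diff(s_grid)
    l_cum = np.concatenate([[0.0], np.cumsum(0.5 * (dl_ds[1:] + dl_ds[:-1]) * ds)])
    Theta = np.concatenate([[0.0], np.cumsum(0.5 * (dTheta_ds[1:] + dTheta_ds[:-1]) * ds)])
    l_free = design.wire_free_length
    if l_cum[-1] < l_free:
        raise DeploymentError(
            "vessel too short for the deployed stent "
            f"(needs wire length {l_free:.4g} m, room for {l_cum[-1]:.4g} m)"
        )
    s_end = float(np.interp(l_free, l_cum, s_grid))
    keep = s_grid <= s_end
    s_dense = np.append(s_grid[keep], s_end)
    Theta_d = np.append(Theta[keep], np.interp(s_end, s_grid, Theta))
    l_d = np.append(l_cum[keep], l_free)
    alpha_d = np.append(alpha[keep], np.interp(s_end, s_grid, alpha))

    dep = DeployedStent(
        design=design, vessel=vessel, start=start_position, end=s_end,
        s_dense=s_dense, Theta=Theta_d, wire_length=l_d, alpha=alpha_d,
        poor_apposition=poor,
    )
    if poor:
        warnings.warn("lumen exceeds nominal diameter by >20%: poor wall apposition")

    # sample wire polylines: shared s sampling fine enough for length checks
    N = design.n_wires // 2
    n_rings = max(int(Theta_d[-1] * N / np.pi), 1)
    n_pts = max(200, samples_per_ring * n_rings)
    s_samp = np.linspace(start_position, s_end, n_pts)
    Th_samp = np.interp(s_samp, s_dense, Theta_d)
    for i in range(N):
        th0 = 2 * np.pi * i / N
        dep.wire_paths.append(_surface_points(vessel, s_samp, th0 + Th_samp))
    for j in range(N):
        th0 = 2 * np.pi * j / N
        dep.wire_paths.append(_surface_points(vessel, s_samp, th0 - Th_samp))
    return dep


@dataclass
class StentCell:
    """One rhombus unit of the deployed braid and its screen quantities."""

    centroid: np.ndarray
    A_t: float
    A_w: float
    side_length: float
    braid_angle: float
    porosity: float
    hydraulic_diameter: float
    arc_position: float
    angle: float  # circumferential position of the centroid (rad)

    @property
    def A_p(self) -> float:
        return self.A_t - self.A_w


def _quad_area(a, b, c, d):
    """Area of 3D quadrilaterals a-b-c-d (vertex order around the rim)."""
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(b - c, d - c), axis=-1)
    return t1 + t2


def extract_cells(
    stent: DeployedStent,
    design: StentDesign | None = None,
    dh_mode: str = "verbatim",
) -> list[StentCell]:
    """Extract one :class:`StentCell` per wire-crossing rhombus.

    Crossings of the two families fall on rings of ``n_wires/2`` points at
    arc positions where the cumulative winding is an integer multiple of
    ``pi/(n_wires/2)``; a cell spans two consecutive ring gaps.  Cell area
    comes from the 3D quadrilateral of its four crossings; wire area is half
    the cell perimeter times the wire diameter minus the crossing-overlap
    parallelogram ``d_w^2/sin(alpha)`` (four quarter-crossings per cell).
    """
    design = design or stent.design
    N = design.n_wires // 2
    if N < 2:
        raise DeploymentError("need at least 2 wires per family")
    d_w = design.wire_diameter
    q_max = int(np.floor(stent.Theta[-1] * N / np.pi))
    if q_max < 2:
        raise DeploymentError("stent too short to form a complete cell")
    q = np.arange(q_max + 1)
    s_ring = np.interp(q * np.pi / N, stent.Theta, stent.s_dense)

    cells: list[StentCell] = []
    vessel = stent.vessel
    for qq in range(q_max - 1):
        iarr = np.arange(N)
        a_ang = (2 * iarr + qq) * np.pi / N
        sA = np.full(N, s_ring[qq])
        sB = np.full(N, s_ring[qq + 1])
        A = _surface_points(vessel, sA, a_ang)
        B = _surface_points(vessel, sB, a_ang + np.pi / N)
        D = _surface_points(vessel, sB, a_ang - np.pi / N)
        if qq + 2 <= q_max:
            sC = np.full(N, s_ring[qq + 2])
            C = _surface_points(vessel, sC, a_ang)
        else:
            break
        area = _quad_area(A, B, C, D)
        e_ab = np.linalg.norm(B - A, axis=1)
        e_ad = np.linalg.norm(D - A, axis=1)
        e_cb = np.linalg.norm(B - C, axis=1)
        e_cd = np.linalg.norm(D - C, axis=1)
        perim = e_ab + e_ad + e_cb + e_cd
        side = perim / 4
        u1 = (B - A) / e_ab[:, None]
        u2 = (D - A) / e_ad[:, None]
        alpha = np.arccos(np.clip(np.sum(u1 * u2, axis=1), -1.0, 1.0))
        centroid = 0.25 * (A + B + C + D)
        s_cent = 0.5 * (s_ring[qq] + s_ring[qq + 2])
        for i in range(N):
            if area[i] < 1e-12:
                continue  # degenerate cell skipped
            aw = 0.5 * perim[i] * d_w - d_w**2 / np.sin(alpha[i])
            aw = min(max(aw, 0.0), area[i])
            eps = porosity(area[i], aw)
            dh = hydraulic_diameter(
                side[i], alpha[i], mode=dh_mode, wire_diameter=d_w
            )
            cells.append(
                StentCell(
                    centroid=centroid[i],
                    A_t=float(area[i]),
                    A_w=float(aw),
                    side_length=float(side[i]),
                    braid_angle=float(alpha[i]),
                    porosity=float(eps),
                    hydraulic_diameter=float(dh),
                    arc_position=float(s_cent),
                    angle=float(np.mod(a_ang[i] + np.pi / 1e12, 2 * np.pi)),
                )
            )
    if not cells:
        raise DeploymentError("no non-degenerate cells extracted")
    return cells


def cells_to_table(cells: list[StentCell]) -> "np.ndarray":
    """Cells as a plain record array for CSV export."""
    dtype = [
        ("x", float), ("y", float), ("z", float), ("A_t", float), ("A_w", float),
        ("side", float), ("alpha", float), ("porosity", float), ("D_h", float),
        ("arc_position", float), ("angle", float),
    ]
    out = np.empty(len(cells), dtype=dtype)
    for k, c in enumerate(cells):
        out[k] = (*c.centroid, c.A_t, c.A_w, c.side_length, c.braid_angle,
                  c.porosity, c.hydraulic_diameter, c.arc_position, c.angle)
    return out
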