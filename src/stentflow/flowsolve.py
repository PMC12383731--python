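"""Steady incompressible finite-volume solver on structured grids.

SIMPLE pressure-velocity coupling on a collocated, uniformly spaced grid
(2D planar or 2D axisymmetric), with Rhie-Chow face interpolation, masked
solid cells (stair-step walls), and the LDPM / coil momentum sinks applied
as per-volume sources linearized each outer iteration:

    S_n = -(C2 |v_n| + C1) v_n / t_eff      (shell, opposes normal flow)
    S   = -(C2_iso |v| + C1_iso) v          (coil, isotropic)

Boundary conditions follow the device-analysis setup: a prescribed inlet
mass flow with a fully developed profile at x-min, a static-pressure outlet
at x-max, and rigid no-slip (or symmetry) walls.  Convection is first-order
upwind, diffusion central; under-relaxation factors are fixed defaults so
runs are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .ldpm import FluidProperties, PorousField

__all__ = [
    "StructuredGrid",
    "BoundaryConditions",
    "FlowField",
    "SolverError",
    "inlet_profile",
    "solve_steady",
]

FLUID, SOLID = 0, 1
REGION_NONE, REGION_SHELL, REGION_SAC = 0, 1, 2

# neighbor codes
_NB_FLUID, _NB_WALL, _NB_SLIP, _NB_INLET, _NB_OUTLET = 0, 1, 2, 3, 4


class SolverError(RuntimeError):
    pass


@dataclass
class BoundaryConditions:
    """Inlet mass flow (kg/s; per meter depth in planar mode), outlet static
    pressure (Pa), and wall treatment on the two y-boundaries."""

    mass_flow: float = 0.003465
    outlet_pressure: float = 0.0
    wall_y0: str = "noslip"
    wall_y1: str = "noslip"

    def __post_init__(self) -> None:
        if self.mass_flow < 0:
            raise SolverError("inlet mass flow must be nonnegative")
        for w in (self.wall_y0, self.wall_y1):
            if w not in ("noslip", "slip"):
                raise SolverError(f"unknown wall type {w!r}")


class StructuredGrid:
    """Uniform collocated grid with cell masks and shell/sac bookkeeping.

    In axisymmetric mode ``y`` is the radial coordinate and all fluxes are
    per radian of azimuth.
    """

    def __init__(
        self, nx: int, ny: int, dx: float, dy: float,
        x0: float = 0.0, y0: float = 0.0, axisymmetric: bool = False,
    ):
        if nx < 2 or ny < 2 or dx <= 0 or dy <= 0:
            raise SolverError("need nx, ny >= 2 and positive spacings")
        self.nx, self.ny, self.dx, self.dy = nx, ny, dx, dy
        self.x0, self.y0 = x0, y0
        self.axisymmetric = axisymmetric
        self.mask = np.zeros((nx, ny), dtype=np.int8)
        self.region = np.zeros((nx, ny), dtype=np.int8)
        self.neck_faces: list[tuple[int, int, int]] = []  # (i, j_face, sign into sac)
        self.shell_mask = np.zeros((nx, ny), dtype=bool)
        self.shell_coords = np.zeros((0, 3))
        self.shell_normal = np.zeros((0, 2))
        self.shell_teff = np.zeros((0,))

    # -- geometry helpers --------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def xc(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def yc(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def yf(self) -> np.ndarray:
        """y positions of the ny+1 y-normal face rows."""
        return self.y0 + np.arange(self.ny + 1) * self.dy

    def face_area_x(self) -> np.ndarray:
        """Area of x-normal faces per row j."""
        if self.axisymmetric:
            return self.yc * self.dy
        return np.full(self.ny, self.dy)

    def face_area_y(self) -> np.ndarray:
        """Area of y-normal faces per face row (ny+1)."""
        if self.axisymmetric:
            return np.abs(self.yf) * self.dx
        return np.full(self.ny + 1, self.dx)

    def volumes(self) -> np.ndarray:
        if self.axisymmetric:
            return np.broadcast_to(self.yc * self.dx * self.dy, (self.nx, self.ny)).copy()
        return np.full((self.nx, self.ny), self.dx * self.dy)

    def fluid_mask(self) -> np.ndarray:
        return self.mask == FLUID

    def mark_shell(
        self, axis: int, position: float, t_shell: float,
        span: tuple[float, float] | None = None,
        coords_fn=None, normal: tuple[float, float] | None = None,
        resolve_width: float | None = None,
        side: str = "centered",
    ) -> None:
        """Mark a one-or-more-layer shell slab normal to ``axis`` at ``position``.

        The marked layer is at least one cell thick: cells whose center lies
        within max(t_shell, h)/2 of the (slightly inward-biased) mid-surface
        are tagged, and each normal column records the total marked thickness
        so the volumetric sink integrates to the intended pressure jump.
        ``resolve_width`` widens the marked slab (the shell-region grid size
        of a refinement study); ``coords_fn(x, y) -> (s, theta, R)`` supplies
        surface coordinates for stent-cell lookup; default uses the
        along-slab coordinate.
        """
        h = self.dy if axis == 1 else self.dx
        width = max(t_shell, h, resolve_width or 0.0)
        X, Y = np.meshgrid(self.xc, self.yc, indexing="ij")
        along = X if axis == 1 else Y
        across = Y if axis == 1 else X
        if side == "below":
            # slab fully on the low-coordinate side of the mid-surface
            # (a wall-apposed device lives inside the lumen)
            dist = np.abs(across - (position - width / 2 - 1e-9 * h))
        else:
            dist = np.abs(across - (position - 1e-9 * h))
        pick = (dist < width / 2) & self.fluid_mask()
        if span is not None:
            pick &= (along >= span[0]) & (along <= span[1])
        if not pick.any():
            raise SolverError(
                "grid does not resolve the shell: refine so at least one cell "
                "layer conforms to the shell region"
            )
        self.shell_mask = pick
        # per-column resolved thickness
        n_layers = pick.sum(axis=axis, keepdims=True)
        teff_full = np.broadcast_to(n_layers * h, pick.shape)
        self.shell_teff = teff_full[pick].astype(float)
        xs, ys = X[pick], Y[pick]
        if coords_fn is None:
            coords = np.column_stack([along[pick], np.zeros(pick.sum()), np.ones(pick.sum())])
        else:
            coords = np.asarray(coords_fn(xs, ys), dtype=float)
        self.shell_coords = coords
        nvec = normal if normal is not None else ((0.0, 1.0) if axis == 1 else (1.0, 0.0))
        self.shell_normal = np.tile(np.asarray(nvec, float), (int(pick.sum()), 1))
        self.region[pick] = np.where(
            self.region[pick] == REGION_NONE, REGION_SHELL, self.region[pick]
        )


@dataclass
class FlowField:
    """Converged (or flagged) solution on a structured grid."""

    grid: StructuredGrid
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    uf: np.ndarray  # x-normal face velocities, (nx+1, ny)
    vf: np.ndarray  # y-normal face velocities, (nx, ny+1)
    residuals: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def inlet_profile(
    bc: BoundaryConditions, grid: StructuredGrid, fluid: FluidProperties
) -> np.ndarray:
    """Fully developed inlet face velocities at x-min, exactly scaled.

    Planar: parabolic between no-slip walls (uniform between slip walls,
    half-parabola for mixed).  Axisymmetric: Hagen-Poiseuille in radius.
    The discrete mass-flow integral is rescaled to match ``bc.mass_flow``
    to machine precision.
    """
    open_j = np.nonzero(grid.mask[0, :] == FLUID)[0]
    if open_j.size == 0:
        raise SolverError("inlet face is completely blocked")
    u_in = np.zeros(grid.ny)
    ylo = grid.y0 + open_j[0] * grid.dy
    yhi = grid.y0 + (open_j[-1] + 1) * grid.dy
    H = yhi - ylo
    y = grid.yc[open_j]
    if grid.axisymmetric:
        R = yhi
        u_in[open_j] = np.maximum(1.0 - (y / R) ** 2, 0.0)
    else:
        t = (y - ylo) / H
        lo_wall = bc.wall_y0 == "noslip" or open_j[0] > 0
        hi_wall = bc.wall_y1 == "noslip" or open_j[-1] < grid.ny - 1
        if lo_wall and hi_wall:
            u_in[open_j] = t * (1.0 - t)
        elif lo_wall:
            u_in[open_j] = t * (2.0 - t)
        elif hi_wall:
            u_in[open_j] = (1.0 - t) * (1.0 + t)
        else:
            u_in[open_j] = 1.0
    Ax = grid.face_area_x()
    flux = fluid.density * np.sum(u_in * Ax)
    target = bc.mass_flow / (2 * np.pi) if grid.axisymmetric else bc.mass_flow
    if flux <= 0:
        if target > 0:
            raise SolverError("inlet profile integrates to zero")
        return u_in
    return u_in * (target / flux)


def _neighbor_codes(grid: StructuredGrid, bc: BoundaryConditions):
    """Neighbor type (fluid/wall/slip/inlet/outlet) per direction."""
    nx, ny = grid.nx, grid.ny
    solid = grid.mask == SOLID
    codes = {}
    for name, shift, axis, bc_code in (
        ("E", -1, 0, _NB_OUTLET),
        ("W", +1, 0, _NB_INLET),
        ("N", -1, 1, _NB_WALL if bc.wall_y1 == "noslip" else _NB_SLIP),
        ("S", +1, 1, _NB_WALL if bc.wall_y0 == "noslip" else _NB_SLIP),
    ):
        c = np.full((nx, ny), bc_code, dtype=np.int8)
        nb_solid = np.roll(solid, shift, axis=axis)
        if name == "E":
            c[:-1, :] = np.where(nb_solid[:-1, :], _NB_WALL, _NB_FLUID)
        elif name == "W":
            c[1:, :] = np.where(nb_solid[1:, :], _NB_WALL, _NB_FLUID)
        elif name == "N":
            c[:, :-1] = np.where(nb_solid[:, :-1], _NB_WALL, _NB_FLUID)
        else:
            c[:, 1:] = np.where(nb_solid[:, 1:], _NB_WALL, _NB_FLUID)
        codes[name] = c
    if grid.axisymmetric and abs(grid.y0) < 1e-15:
        # the axis is a symmetry line regardless of the configured wall type
        axis_row = codes["S"][:, 0]
        axis_row[axis_row != _NB_FLUID] = _NB_SLIP
    return codes


def _face_pressure_x(grid, p, fluidm, p_out):
    nx, ny = grid.nx, grid.ny
    pf = np.zeros((nx + 1, ny))
    pf[1:nx, :] = 0.5 * (p[:-1, :] + p[1:, :])
    left_solid = ~fluidm[:-1, :]
    right_solid = ~fluidm[1:, :]
    pf[1:nx, :][left_solid] = p[1:, :][left_solid]
    pf[1:nx, :][right_solid] = p[:-1, :][right_solid]
    pf[0, :] = p[0, :]
    pf[nx, :] = np.where(fluidm[-1, :], p_out, p[-1, :])
    return pf


def _face_pressure_y(grid, p, fluidm):
    nx, ny = grid.nx, grid.ny
    pf = np.zeros((nx, ny + 1))
    pf[:, 1:ny] = 0.5 * (p[:, :-1] + p[:, 1:])
    lo_solid = ~fluidm[:, :-1]
    hi_solid = ~fluidm[:, 1:]
    pf[:, 1:ny][lo_solid] = p[:, 1:][lo_solid]
    pf[:, 1:ny][hi_solid] = p[:, :-1][hi_solid]
    pf[:, 0] = p[:, 0]
    pf[:, ny] = p[:, -1]
    return pf


def _shear_rate(grid, u, v, fluidm):
    """Cell strain-rate magnitude sqrt(2 D:D) with zero velocity in solids."""
    uu = np.where(fluidm, u, 0.0)
    vv = np.where(fluidm, v, 0.0)
    dudx, dudy = np.gradient(uu, grid.dx, grid.dy)
    dvdx, dvdy = np.gradient(vv, grid.dx, grid.dy)
    dxy = 0.5 * (dudy + dvdx)
    return np.sqrt(2 * (dudx**2 + dvdy**2 + 2 * dxy**2))


def solve_steady(
    grid: StructuredGrid,
    porous: PorousField | None,
    fluid: FluidProperties,
    bc: BoundaryConditions,
    tol: float = 1e-6,
    max_iter: int = 10000,
    relax_u: float = 0.7,
    relax_p: float = 0.3,
    convection: str = "central",
    quiet: bool = True,
) -> FlowField:
    """SIMPLE iteration to a steady solution.

    Converged when the normalized momentum and continuity residuals all fall
    below ``tol``; the field is returned flagged unconverged otherwise.
    Convection is second-order central by deferred correction on an implicit
    upwind stencil (``convection="upwind"`` falls back to pure first order).
    Raises :class:`SolverError` on residual blow-up (x1000 over the best).
    """
    if convection not in ("central", "upwind"):
        raise SolverError(f"unknown convection scheme {convection!r}")
    central = convection == "central"
    nx, ny = grid.nx, grid.ny
    if porous is None:
        porous = PorousField.empty((nx, ny))
    fluidm = grid.fluid_mask()
    nf = int(fluidm.sum())
    if nf == 0:
        raise SolverError("no fluid cells")
    cid = -np.ones((nx, ny), dtype=np.int64)
    cid[fluidm] = np.arange(nf)
    V = grid.volumes()
    Ax = grid.face_area_x()           # per j
    Ay = grid.face_area_y()           # per face row
    dx, dy = grid.dx, grid.dy
    rho = fluid.density
    codes = _neighbor_codes(grid, bc)
    u_in = inlet_profile(bc, grid, fluid)
    m_in = rho * np.sum(u_in[fluidm[0, :]] * Ax[fluidm[0, :]])

    # Reynolds sanity check on the inlet span
    open_j = np.nonzero(fluidm[0, :])[0]
    H_in = (open_j[-1] - open_j[0] + 1) * dy
    mu0 = float(np.asarray(fluid.mu(0.0)))
    Re = rho * (np.max(u_in) if u_in.size else 0.0) * H_in / mu0
    if Re > 2000:
        warnings.warn(f"inlet Reynolds number {Re:.0f} above laminar range")

    u = np.zeros((nx, ny))
    v = np.zeros((nx, ny))
    p = np.zeros((nx, ny))
    u[fluidm] = float(np.mean(u_in[open_j])) if open_j.size else 0.0
    uf = np.zeros((nx + 1, ny))
    vf = np.zeros((nx, ny + 1))
    uf[0, :] = u_in
    inner_x = fluidm[:-1, :] & fluidm[1:, :]
    uf[1:nx, :][inner_x] = float(np.mean(u_in[open_j])) if open_j.size else 0.0
    uf[nx, :] = np.where(fluidm[-1, :], u_in.mean() if open_j.size else 0.0, 0.0)
    inner_y = fluidm[:, :-1] & fluidm[:, 1:]

    # index bookkeeping for sparse assembly
    cidE = np.full((nx, ny), -1, dtype=np.int64)
    cidE[:-1, :] = cid[1:, :]
    cidW = np.full((nx, ny), -1, dtype=np.int64)
    cidW[1:, :] = cid[:-1, :]
    cidN = np.full((nx, ny), -1, dtype=np.int64)
    cidN[:, :-1] = cid[:, 1:]
    cidS = np.full((nx, ny), -1, dtype=np.int64)
    cidS[:, 1:] = cid[:, :-1]

    Ax2 = np.broadcast_to(Ax, (nx, ny))
    AyS = np.broadcast_to(Ay[:ny], (nx, ny))     # south face of each cell
    AyN = np.broadcast_to(Ay[1 : ny + 1], (nx, ny))
    yc2 = np.broadcast_to(grid.yc, (nx, ny))

    residuals: list[tuple[float, float, float]] = []
    converged = False
    best = np.inf
    mu_cell = np.full((nx, ny), mu0)
    p_out = bc.outlet_pressure
    d_coef = np.where(fluidm, V / max(mu0, 1e-30), 0.0)  # placeholder until first solve

    def faces_from(uc, vc, pc, dcoef):
        """Rhie-Chow face velocities with boundary handling."""
        pfx = _face_pressure_x(grid, pc, fluidm, p_out)
        pfy = _face_pressure_y(grid, pc, fluidm)
        gpx = (pfx[1:, :] - pfx[:-1, :]) / dx
        gpy = (pfy[:, 1:] - pfy[:, :-1]) / dy
        ufn = np.zeros_like(uf)
        vfn = np.zeros_like(vf)
        dW = dcoef[:-1, :]
        dE = dcoef[1:, :]
        davg = 0.5 * (dW + dE)
        ufn[1:nx, :] = 0.5 * (uc[:-1, :] + uc[1:, :]) - davg * (
            (pc[1:, :] - pc[:-1, :]) / dx - 0.5 * (gpx[:-1, :] + gpx[1:, :])
        )
        ufn[1:nx, :][~inner_x] = 0.0
        ufn[0, :] = u_in
        ufn[nx, :] = np.where(fluidm[-1, :], uc[-1, :], 0.0)
        dS = dcoef[:, :-1]
        dN = dcoef[:, 1:]
        davy = 0.5 * (dS + dN)
        vfn[:, 1:ny] = 0.5 * (vc[:, :-1] + vc[:, 1:]) - davy * (
            (pc[:, 1:] - pc[:, :-1]) / dy - 0.5 * (gpy[:, :-1] + gpy[:, 1:])
        )
        vfn[:, 1:ny][~inner_y] = 0.0
        # outlet mass conservation: scale outflow to match inflow
        out_m = fluidm[-1, :]
        m_out = rho * np.sum(ufn[nx, out_m] * Ax[out_m])
        if m_in > 0:
            if m_out > 1e-12 * m_in:
                ufn[nx, out_m] *= m_in / m_out
            else:
                ufn[nx, out_m] += (m_in - m_out) / (rho * np.sum(Ax[out_m]))
        return ufn, vfn, gpx, gpy

    def momentum_coeffs(comp, ufc, vfc, gpx, gpy, uc, vc):
        """Assemble unrelaxed aP, neighbor coefficients and source for u or v."""
        Fe = rho * ufc[1:, :] * Ax2
        Fw = rho * ufc[:-1, :] * Ax2
        Fn = rho * vfc[:, 1:] * AyN
        Fs = rho * vfc[:, :-1] * AyS
        De = mu_cell * Ax2 / dx
        Dw = mu_cell * Ax2 / dx
        Dn = mu_cell * AyN / dy
        Ds = mu_cell * AyS / dy
        aP = np.zeros((nx, ny))
        b = np.zeros((nx, ny))
        nb_terms = []
        phi_in = u_in[None, :] if comp == "u" else 0.0
        for name, F_out, D, cnb in (
            ("E", Fe, De, cidE), ("W", -Fw, Dw, cidW),
            ("N", Fn, Dn, cidN), ("S", -Fs, Ds, cidS),
        ):
            code = codes[name]
            interior = code == _NB_FLUID
            a_nb = np.where(interior, D + np.maximum(-F_out, 0.0), 0.0)
            aP += np.where(interior, D + np.maximum(F_out, 0.0), 0.0)
            wall = code == _NB_WALL
            aP += np.where(wall, 2.0 * D, 0.0)
            if comp == "v":
                aP += np.where(code == _NB_SLIP, 2.0 * D, 0.0)
            inlet = code == _NB_INLET
            if np.any(inlet):
                aP += np.where(inlet, 2.0 * D + np.maximum(F_out, 0.0), 0.0)
                a_b = np.where(inlet, 2.0 * D + np.maximum(-F_out, 0.0), 0.0)
                b += a_b * (phi_in if comp == "u" else 0.0)
            outlet = code == _NB_OUTLET
            aP += np.where(outlet, np.maximum(F_out, 0.0), 0.0)
            nb_terms.append((cnb, a_nb))
        if central:
            # deferred-correction central differencing on interior faces:
            # implicit upwind above, explicit (central - upwind) here, which
            # removes the first-order numerical diffusion at convergence
            phi = uc if comp == "u" else vc
            fx = rho * ufc[1:-1, :] * Ax2[:-1, :]          # interior x-faces
            phi_u = np.where(fx > 0, phi[:-1, :], phi[1:, :])
            corr_x = np.where(inner_x, fx * (0.5 * (phi[:-1, :] + phi[1:, :]) - phi_u), 0.0)
            fy = rho * vfc[:, 1:-1] * AyN[:, :-1]          # interior y-faces
            phi_uy = np.where(fy > 0, phi[:, :-1], phi[:, 1:])
            corr_y = np.where(inner_y, fy * (0.5 * (phi[:, :-1] + phi[:, 1:]) - phi_uy), 0.0)
            div = np.zeros((nx, ny))
            div[1:, :] -= corr_x          # west-face contribution (outward = -F)
            div[:-1, :] += corr_x         # east face
            div[:, 1:] -= corr_y
            div[:, :-1] += corr_y
            b -= div
        # pressure force
        b += (-gpx if comp == "u" else -gpy) * V
        # porous sinks, linearized per outer iteration.  The shell (screen)
        # force uses the face-interpolated normal velocity — the
        # mass-conserving through-flow — with the cell velocity only in the
        # implicit stabilizing part (deferred correction), so the integrated
        # pressure jump matches the screen correlation even when the shell
        # is a single cell layer thick.
        ucf = 0.5 * (ufc[:-1, :] + ufc[1:, :])
        vcf = 0.5 * (vfc[:, :-1] + vfc[:, 1:])
        nxv = porous.normal[..., 0]
        nyv = porous.normal[..., 1]
        vn_f = ucf * nxv + vcf * nyv
        Kn = (porous.C2 * np.abs(vn_f) + porous.C1) / porous.t_eff
        speed = np.hypot(uc, vc)
        Ki = porous.C2_iso * speed + porous.C1_iso
        if comp == "u":
            aP += (Kn * nxv**2 + Ki) * V
            b += -(Kn * nxv * (vn_f - nxv * uc)) * V
        else:
            aP += (Kn * nyv**2 + Ki) * V
            b += -(Kn * nyv * (vn_f - nyv * vc)) * V
            if grid.axisymmetric:
                aP += mu_cell * V / yc2**2
        return aP, nb_terms, b

    def sparse_solve(aP, nb_terms, b, phi_old, relax):
        aPr = aP / relax
        br = b + (1.0 - relax) * aPr * phi_old
        rows = [cid[fluidm]]
        cols = [cid[fluidm]]
        data = [aPr[fluidm]]
        for cnb, a_nb in nb_terms:
            m = fluidm & (cnb >= 0) & (a_nb != 0)
            rows.append(cid[m])
            cols.append(cnb[m])
            data.append(-a_nb[m])
        A = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nf, nf),
        )
        sol = spla.spsolve(A, br[fluidm])
        out = np.zeros((nx, ny))
        out[fluidm] = sol
        return out

    for it in range(1, max_iter + 1):
        if fluid.viscosity_law is not None:
            mu_cell = np.broadcast_to(
                np.asarray(fluid.mu(_shear_rate(grid, u, v, fluidm))), (nx, ny)
            ).copy()
        pfx = _face_pressure_x(grid, p, fluidm, p_out)
        pfy = _face_pressure_y(grid, p, fluidm)
        gpx = (pfx[1:, :] - pfx[:-1, :]) / dx
        gpy = (pfy[:, 1:] - pfy[:, :-1]) / dy

        aPu, nbu, bu = momentum_coeffs("u", uf, vf, gpx, gpy, u, v)
        aPv, nbv, bv = momentum_coeffs("v", uf, vf, gpx, gpy, u, v)

        # normalized residuals of the unrelaxed equations at the current state
        def _gather(phi, cnb):
            out = np.zeros((nx, ny))
            m = cnb >= 0
            flat = phi[fluidm]
            out[m] = flat[cnb[m]]
            return out

        def resid(aP, nb_terms, b, phi):
            r = b - aP * phi
            for cnb, a_nb in nb_terms:
                r += a_nb * _gather(phi, cnb)
            scale = np.sum(np.abs(aP[fluidm] * phi[fluidm]))
            scale = max(scale, m_in * max(np.max(np.abs(u_in)), 1e-30), 1e-30)
            return float(np.sum(np.abs(r[fluidm])) / scale)

        res_u = resid(aPu, nbu, bu, u)
        res_v = resid(aPv, nbv, bv, v)

        u_new = sparse_solve(aPu, nbu, bu, u, relax_u)
        v_new = sparse_solve(aPv, nbv, bv, v, relax_u)
        d_coef = np.where(fluidm, V / (aPu / relax_u + 1e-300), 0.0)
        u, v = u_new, v_new

        uf, vf, gpx, gpy = faces_from(u, v, p, d_coef)

        # pressure correction
        Fe = rho * uf[1:, :] * Ax2
        Fw = rho * uf[:-1, :] * Ax2
        Fn = rho * vf[:, 1:] * AyN
        Fs = rho * vf[:, :-1] * AyS
        imb = Fe - Fw + Fn - Fs
        res_c = float(np.sum(np.abs(imb[fluidm])) / max(m_in, 1e-30))
        residuals.append((res_u, res_v, res_c))

        worst = max(res_u, res_v, res_c)
        best = min(best, worst)
        if worst > 1e3 * best and it > 20 and worst > 1.0:
            raise SolverError(
                f"solver divergence at iteration {it}: residuals "
                f"u={res_u:.3g} v={res_v:.3g} c={res_c:.3g}"
            )
        if it >= 2 and worst < tol:
            converged = True
            break

        # p' coefficients on interior faces
        EfX = np.zeros((nx + 1, ny))
        davg = 0.5 * (d_coef[:-1, :] + d_coef[1:, :])
        EfX[1:nx, :] = np.where(inner_x, rho * Ax2[:-1, :] * davg / dx, 0.0)
        out_m = fluidm[-1, :]
        E_out = np.where(out_m, rho * Ax * d_coef[-1, :] / (dx / 2.0), 0.0)
        EfY = np.zeros((nx, ny + 1))
        davy = 0.5 * (d_coef[:, :-1] + d_coef[:, 1:])
        EfY[:, 1:ny] = np.where(inner_y, rho * AyN[:, :-1] * davy / dy, 0.0)

        aPp = np.zeros((nx, ny))
        aPp += EfX[1:, :] + EfX[:-1, :] + EfY[:, 1:] + EfY[:, :-1]
        aPp[-1, :] += E_out
        aPp = np.where(fluidm & (aPp > 0), aPp, np.where(fluidm, 1.0, 0.0))
        nbp = [
            (cidE, EfX[1:, :]), (cidW, EfX[:-1, :]),
            (cidN, EfY[:, 1:]), (cidS, EfY[:, :-1]),
        ]
        rows = [cid[fluidm]]
        cols = [cid[fluidm]]
        data = [aPp[fluidm]]
        for cnb, a_nb in nbp:
            m = fluidm & (cnb >= 0) & (a_nb != 0)
            rows.append(cid[m])
            cols.append(cnb[m])
            data.append(-a_nb[m])
        Ap = sp.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nf, nf),
        )
        pc = np.zeros((nx, ny))
        pc[fluidm] = spla.spsolve(Ap, -imb[fluidm])

        # corrections
        p = p + relax_p * pc
        pcE = _gather(pc, cidE)
        pcW = _gather(pc, cidW)
        pcN = _gather(pc, cidN)
        pcS = _gather(pc, cidS)
        uf[1:nx, :] -= np.where(inner_x, davg * (pc[1:, :] - pc[:-1, :]) / dx, 0.0)
        uf[nx, :] += np.where(out_m, d_coef[-1, :] * pc[-1, :] / (dx / 2.0), 0.0)
        vf[:, 1:ny] -= np.where(inner_y, davy * (pc[:, 1:] - pc[:, :-1]) / dy, 0.0)
        # cell corrections with one-sided differences at boundaries
        pfcx = _face_pressure_x(grid, pc, fluidm, 0.0)
        pfcy = _face_pressure_y(grid, pc, fluidm)
        u = u - d_coef * (pfcx[1:, :] - pfcx[:-1, :]) / dx
        v = v - d_coef * (pfcy[:, 1:] - pfcy[:, :-1]) / dy
        u[~fluidm] = 0.0
        v[~fluidm] = 0.0

    return FlowField(
        grid=grid, u=u, v=v, p=p, uf=uf, vf=vf,
        residuals=residuals, converged=converged, iterations=len(residuals),
    )
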