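"""Case configuration, fixture geometries and end-to-end scenario running.

A case ties the whole pipeline together: build an idealized vessel with a
sidewall sac, deploy the braided stent on the 3D lumen surface, extract the
braid cells, project their screen coefficients onto a planar channel grid
whose streamwise coordinate is the vessel arc length, solve the steady flow
and evaluate the sac metrics.  The planar channel preserves the tube's mean
velocity (inlet mass flow per unit depth is rescaled accordingly) and the
neck plane lies on the original wall line, so inflow and turnover are
well-defined desk-scale analogues of their 3D counterparts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .flowsolve import (
    FLUID,
    REGION_SAC,
    SOLID,
    BoundaryConditions,
    FlowField,
    StructuredGrid,
    solve_steady,
)
from .geometry import AneurysmSpec, attach_aneurysm, make_curved_vessel, make_straight_vessel
from .hemodyn import HemoMetrics, change_rate, compute_metrics
from .ldpm import CoilFill, FluidProperties, PorousField, build_coil_region, build_porous_field
from .stent import StentDesign, deploy_stent, extract_cells, local_braid_angle
from .vtkio import write_polylines_vtk, write_structured_vtk
from .wireoracle import pressure_drop

__all__ = [
    "CaseConfig",
    "GeometryConfig",
    "AneurysmConfig",
    "StentConfig",
    "CoilConfig",
    "SolverConfig",
    "CaseResult",
    "default_config",
    "run_case",
    "grid_dependence",
    "scenario_table",
    "standard_scenarios",
    "build_duct_screen_case",
    "load_config",
    "save_config",
]


class WorkbenchError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# configuration


@dataclass
class AneurysmConfig:
    dome_radius: float = 2.5e-3
    neck_radius: float = 1.25e-3
    position: float | None = None  # arc position of the neck center; None = mid


@dataclass
class GeometryConfig:
    kind: str = "straight"          # 'straight' | 'curved'
    radius: float = 2.0e-3
    length: float = 32e-3           # straight length / arc length target
    spacing: float = 2.5e-4
    bend_radius: float = 12e-3
    bend_angle: float = float(np.pi / 2)
    aneurysm: AneurysmConfig | None = field(default_factory=AneurysmConfig)


@dataclass
class StentConfig:
    enabled: bool = True
    n_wires: int = 48
    wire_diameter: float = 30e-6
    nominal_diameter: float = 4.5e-3
    nominal_length: float = 10e-3
    braid_angle_deg: float = 150.0
    start: float | None = None      # None = center the deployed span on the neck
    dh_mode: str = "verbatim"
    intersections_zero: bool = False


@dataclass
class CoilConfig:
    n_coils: int = 0
    ver: float | None = None        # overrides n_coils when given
    coil_wire_diameter: float = 0.25e-3
    coil_length: float = 0.20
    # coils settle in the dome fundus, downstream of the neck: sac cells
    # below this fraction of the dome radius above the neck plane stay
    # coil-free.  None places the coil region above the dome equator.
    neck_clearance_fraction: float | None = None


@dataclass
class SolverConfig:
    cell_size: float = 2.0e-4       # streamwise spacing dx
    cell_size_y: float = 1.0e-4     # cross-stream spacing dy (shell-region size)
    tol: float = 1e-5
    max_iter: int = 2500
    relax_u: float = 0.7
    relax_p: float = 0.3
    # width over which the shell sink is smeared (None = one grid layer);
    # the knob a porous-region grid study varies
    shell_layer_width: float | None = None


@dataclass
class CaseConfig:
    name: str = "straight_sidewall"
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    stent: StentConfig = field(default_factory=StentConfig)
    coil: CoilConfig = field(default_factory=CoilConfig)
    density: float = 1100.0
    viscosity: float = 3.6e-3
    mass_flow: float = 0.003465     # tube mass flow (kg/s); sets the mean velocity
    outlet_pressure: float = 0.0
    solver: SolverConfig = field(default_factory=SolverConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        d = dict(d)
        geo = dict(d.get("geometry", {}))
        an = geo.get("aneurysm")
        geo["aneurysm"] = AneurysmConfig(**an) if an else None
        return cls(
            name=d.get("name", "case"),
            geometry=GeometryConfig(**geo),
            stent=StentConfig(**d.get("stent", {})),
            coil=CoilConfig(**d.get("coil", {})),
            density=d.get("density", 1100.0),
            viscosity=d.get("viscosity", 3.6e-3),
            mass_flow=d.get("mass_flow", 0.003465),
            outlet_pressure=d.get("outlet_pressure", 0.0),
            solver=SolverConfig(**d.get("solver", {})),
            seed=d.get("seed", 0),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def fluid(self) -> FluidProperties:
        return FluidProperties(density=self.density, viscosity=self.viscosity)


def load_config(path) -> CaseConfig:
    with open(path) as fh:
        return CaseConfig.from_dict(yaml.safe_load(fh))


def save_config(config: CaseConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def default_config(name: str = "straight_sidewall") -> CaseConfig:
    """Bundled fixture configurations sized so every case runs in minutes."""
    if name == "straight_sidewall":
        return CaseConfig(name=name)
    if name == "curved_sidewall":
        cfg = CaseConfig(name=name)
        cfg.geometry = GeometryConfig(
            kind="curved", radius=2.0e-3, bend_radius=12e-3,
            bend_angle=float(np.pi / 2), spacing=2.5e-4,
            aneurysm=AneurysmConfig(dome_radius=2.0e-3, neck_radius=1.0e-3),
        )
        cfg.stent.nominal_length = 6e-3
        return cfg
    if name == "untreated_sidewall":
        cfg = CaseConfig(name=name)
        cfg.stent.enabled = False
        return cfg
    raise WorkbenchError(f"unknown fixture {name!r}")


# --------------------------------------------------------------------------
# case assembly


@dataclass
class CaseResult:
    config: CaseConfig
    metrics: HemoMetrics
    flow: FlowField
    grid: StructuredGrid
    cells: list | None
    deployment: object | None
    sac_volume_3d: float | None
    timings: dict[str, float]


def _build_vessel(geo: GeometryConfig):
    if geo.kind == "straight":
        return make_straight_vessel(geo.radius, geo.length, geo.spacing)
    if geo.kind == "curved":
        return make_curved_vessel(geo.radius, geo.bend_radius, geo.bend_angle, geo.spacing)
    raise WorkbenchError(f"unknown geometry kind {geo.kind!r}")


def _sac_volume_3d(spec: AneurysmSpec) -> float:
    """Analytic sac volume: dome sphere minus the cap below the neck plane."""
    r = spec.dome_radius
    h_off = np.sqrt(r**2 - spec.neck_radius**2)
    h_cap = r - h_off
    return float(4.0 / 3.0 * np.pi * r**3 - np.pi * h_cap**2 * (3 * r - h_cap) / 3.0)


def build_case(config: CaseConfig):
    """Assemble grid, porous field and boundary conditions for a case."""
    geo = config.geometry
    vessel = _build_vessel(geo)
    L = vessel.length
    R = geo.radius
    H = 2 * R
    sol = config.solver
    ny_ch = max(int(round(H / sol.cell_size_y)), 4)
    dy = H / ny_ch
    nx = max(int(round(L / sol.cell_size)), 8)
    dx = L / nx

    an = geo.aneurysm
    attachment = None
    if an is not None:
        x_n = an.position if an.position is not None else L / 2
        spec = AneurysmSpec(an.dome_radius, an.neck_radius, x_n)
        attachment = attach_aneurysm(vessel, spec)
        h_off = np.sqrt(an.dome_radius**2 - an.neck_radius**2)
        cy = H + h_off
        top = cy + an.dome_radius + 2 * dy
        ny = ny_ch + int(np.ceil((top - H) / dy))
    else:
        x_n = L / 2
        ny = ny_ch

    grid = StructuredGrid(nx, ny, dx, dy)
    X, Y = np.meshgrid(grid.xc, grid.yc, indexing="ij")
    fluid_cells = Y < H
    if an is not None:
        in_sac_circle = (X - x_n) ** 2 + (Y - cy) ** 2 <= an.dome_radius**2
        fluid_cells |= in_sac_circle
        grid.region[in_sac_circle & (Y > H)] = REGION_SAC
    grid.mask[~fluid_cells] = SOLID
    jf = ny_ch
    if an is not None:
        for i in range(nx):
            if grid.mask[i, jf - 1] == FLUID and jf < ny and grid.mask[i, jf] == FLUID:
                grid.neck_faces.append((i, jf, +1))
        if not grid.neck_faces:
            raise WorkbenchError("aneurysm neck not resolved by the grid")

    # planar channel preserving the tube mean velocity
    m2d = 2.0 * config.mass_flow / (np.pi * R)
    bc = BoundaryConditions(mass_flow=m2d, outlet_pressure=config.outlet_pressure)

    fluid = config.fluid()
    porous = PorousField.empty(grid.shape)
    deployment, cells = None, None
    if config.stent.enabled:
        design = StentDesign(
            n_wires=config.stent.n_wires,
            wire_diameter=config.stent.wire_diameter,
            nominal_diameter=config.stent.nominal_diameter,
            nominal_length=config.stent.nominal_length,
            nominal_braid_angle=float(np.deg2rad(config.stent.braid_angle_deg)),
        )
        a_loc = local_braid_angle(design, R)
        dep_len = design.wire_free_length * float(np.cos(a_loc / 2))
        start = config.stent.start
        if start is None:
            start = max(x_n - dep_len / 2, vessel.arc_length[1])
        deployment = deploy_stent(design, vessel, start)
        cells = extract_cells(deployment, design, dh_mode=config.stent.dh_mode)
        grid.mark_shell(
            axis=1, position=H, t_shell=design.shell_thickness,
            span=deployment.coverage_span,
            coords_fn=lambda xs, ys: np.column_stack(
                [xs, np.zeros_like(xs), np.full_like(xs, R)]
            ),
            resolve_width=sol.shell_layer_width,
            side="below",
        )
        porous = build_porous_field(
            cells, grid, design.shell_thickness, fluid,
            intersections_zero=config.stent.intersections_zero,
            wire_diameter=design.wire_diameter,
        )

    if an is not None and (config.coil.n_coils > 0 or config.coil.ver):
        v3d = _sac_volume_3d(AneurysmSpec(an.dome_radius, an.neck_radius, x_n))
        if config.coil.ver is not None:
            cf = CoilFill(
                config.coil.coil_wire_diameter, config.coil.coil_length, config.coil.ver
            )
        else:
            cf = CoilFill.from_coils(
                config.coil.n_coils, v3d,
                config.coil.coil_wire_diameter, config.coil.coil_length,
            )
        frac = config.coil.neck_clearance_fraction
        if frac is None:
            frac = float(np.sqrt(an.dome_radius**2 - an.neck_radius**2) / an.dome_radius)
        clearance = frac * an.dome_radius
        coil_mask = (grid.region == REGION_SAC) & (Y > H + clearance)
        if not coil_mask.any():
            coil_mask = grid.region == REGION_SAC
        porous = porous.add(build_coil_region(cf, coil_mask, fluid))

    return grid, porous, bc, vessel, attachment, deployment, cells


def run_case(config: CaseConfig, outdir=None) -> CaseResult:
    """Run a case end to end; optionally write CSV/VTK/manifest artifacts.

    Raises :class:`WorkbenchError` when the solve does not converge, so CLI
    wrappers exit nonzero.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    grid, porous, bc, vessel, attachment, deployment, cells = build_case(config)
    timings["setup"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sol = config.solver
    flow = solve_steady(
        grid, porous, config.fluid(), bc,
        tol=sol.tol, max_iter=sol.max_iter,
        relax_u=sol.relax_u, relax_p=sol.relax_p,
    )
    timings["solve"] = time.perf_counter() - t0
    if not flow.converged:
        raise WorkbenchError(
            f"solver did not converge in {flow.iterations} iterations "
            f"(last residuals {flow.residuals[-1]})"
        )

    t0 = time.perf_counter()
    if config.geometry.aneurysm is not None:
        metrics = compute_metrics(flow)
        sac3d = _sac_volume_3d(
            AneurysmSpec(
                config.geometry.aneurysm.dome_radius,
                config.geometry.aneurysm.neck_radius,
                vessel.length / 2,
            )
        )
    else:
        fluidm = grid.fluid_mask()
        metrics = HemoMetrics(
            mean_velocity=float(np.mean(flow.speed()[fluidm])),
            mean_shear_rate=float("nan"),
            inflow_rate=float(bc.mass_flow / config.density),
            turnover_time=float("nan"),
            sac_volume=0.0,
        )
        sac3d = None
    timings["metrics"] = time.perf_counter() - t0

    result = CaseResult(
        config=config, metrics=metrics, flow=flow, grid=grid, cells=cells,
        deployment=deployment, sac_volume_3d=sac3d, timings=timings,
    )
    if outdir is not None:
        _write_artifacts(result, porous, Path(outdir))
    return result


def _write_artifacts(result: CaseResult, porous: PorousField, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([result.metrics.as_dict()]).to_csv(outdir / "metrics.csv", index=False)
    pd.DataFrame(
        result.flow.residuals, columns=["res_u", "res_v", "res_continuity"]
    ).to_csv(outdir / "residuals.csv", index=False)
    write_structured_vtk(
        outdir / "field.vtk",
        result.grid,
        {
            "velocity": np.stack([result.flow.u, result.flow.v], axis=-1),
            "pressure": result.flow.p,
            "region": result.grid.region.astype(float),
            "C1": porous.C1 + porous.C1_iso,
            "C2": porous.C2 + porous.C2_iso,
        },
    )
    if result.deployment is not None:
        write_polylines_vtk(outdir / "wires.vtk", result.deployment.wire_paths)
    if result.cells is not None:
        from .stent import cells_to_table

        pd.DataFrame(cells_to_table(result.cells)).to_csv(outdir / "cells.csv", index=False)
    manifest = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "versions": {"stentflow": _pkg_version, "numpy": np.__version__},
        "iterations": result.flow.iterations,
        "timings_s": result.timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        for stage, dt in result.timings.items():
            fh.write(f"{stage}: {dt:.3f} s\n")
        fh.write(f"iterations: {result.flow.iterations}\n")


# --------------------------------------------------------------------------
# harnesses


def grid_dependence(
    config: CaseConfig, levels: list[float], mode: str = "shell"
) -> tuple[pd.DataFrame, float]:
    """Porous-region grid study: sac velocity vs shell-region resolution.

    ``mode='shell'`` mirrors the way such studies vary only the porous
    region: the bulk grid stays fixed and each level sets the width over
    which the shell resistance is resolved (smeared), the shell-region grid
    size.  ``mode='grid'`` refines both cell sizes proportionally instead.
    Levels are meters, sorted coarse to fine internally, so the reported
    converged level is independent of input order.  The metric is the sac
    mean velocity.  Returns the table and the coarsest level whose change
    against the next-coarser level is below 2%.
    """
    if len(levels) < 3:
        raise WorkbenchError("grid dependence needs at least 3 refinement levels")
    if mode not in ("shell", "grid"):
        raise WorkbenchError(f"unknown grid-dependence mode {mode!r}")
    levels = sorted(set(levels), reverse=True)
    rows = []
    prev = None
    aspect = config.solver.cell_size / config.solver.cell_size_y
    for lv in levels:
        cfg = CaseConfig.from_dict(config.to_dict())
        if mode == "shell":
            cfg.solver.shell_layer_width = lv
        else:
            cfg.solver.cell_size_y = lv
            cfg.solver.cell_size = lv * aspect
        try:
            res = run_case(cfg)
            if config.geometry.aneurysm is not None:
                val = res.metrics.mean_velocity
            else:
                val = np.nan
            if mode == "shell":
                n_cells = int(res.grid.shell_mask.sum())
            else:
                n_cells = int(res.grid.fluid_mask().sum())
            ok = True
        except WorkbenchError:
            val, n_cells, ok = np.nan, 0, False
        diff = (
            abs(change_rate(val, prev, decimals=None))
            if (prev is not None and ok and np.isfinite(val))
            else np.nan
        )
        rows.append(
            {"cell_size_y": lv, "n_cells": n_cells, "metric": val,
             "diff_pct": diff, "converged": ok}
        )
        if ok:
            prev = val
    table = pd.DataFrame(rows)
    conv = table[(table.diff_pct < 2.0)]
    converged_level = float(conv.cell_size_y.iloc[0]) if len(conv) else float("nan")
    return table, converged_level


def standard_scenarios(base: CaseConfig) -> dict[str, CaseConfig]:
    """Treatment-planning variants: resized/repositioned device and coils."""
    out: dict[str, CaseConfig] = {}

    def clone() -> CaseConfig:
        return CaseConfig.from_dict(base.to_dict())

    a = clone()
    a.name = "position_A_5.0"
    a.stent.nominal_diameter = 5.0e-3
    out[a.name] = a
    b = clone()
    b.name = "position_B_5.0"
    b.stent.nominal_diameter = 5.0e-3
    geo = b.geometry
    x_n = geo.aneurysm.position if geo.aneurysm.position is not None else geo.length / 2
    design = StentDesign(
        n_wires=b.stent.n_wires, wire_diameter=b.stent.wire_diameter,
        nominal_diameter=b.stent.nominal_diameter, nominal_length=b.stent.nominal_length,
        nominal_braid_angle=float(np.deg2rad(b.stent.braid_angle_deg)),
    )
    a_loc = local_braid_angle(design, geo.radius)
    dep_len = design.wire_free_length * float(np.cos(a_loc / 2))
    b.stent.start = max(x_n - dep_len / 2 + 2e-3, 2.5e-4)
    out[b.name] = b
    c1 = clone()
    c1.name = "one_coil"
    c1.coil.n_coils = 1
    c1.coil.ver = 0.012
    out[c1.name] = c1
    c2 = clone()
    c2.name = "two_coils"
    c2.coil.n_coils = 2
    c2.coil.ver = 0.024
    out[c2.name] = c2
    return out


def scenario_table(
    base: CaseConfig, variants: dict[str, CaseConfig]
) -> tuple[pd.DataFrame, dict[str, CaseResult]]:
    """Per-variant metrics and change rates against the baseline.

    All variants must share the baseline's geometry.
    """
    base_geo = dataclasses.asdict(base.geometry)
    for label, cfg in variants.items():
        if dataclasses.asdict(cfg.geometry) != base_geo:
            raise WorkbenchError(f"variant {label!r} changes the geometry")
    results = {"baseline": run_case(base)}
    for label, cfg in variants.items():
        results[label] = run_case(cfg)
    metric_keys = ("mean_velocity", "mean_shear_rate", "inflow_rate", "turnover_time")
    rows = []
    bm = results["baseline"].metrics.as_dict()
    for label, res in results.items():
        m = res.metrics.as_dict()
        row = {"case": label}
        for k in metric_keys:
            row[k] = m[k]
            row[f"{k}_change_pct"] = (
                0.0 if label == "baseline" else change_rate(m[k], bm[k])
            )
        rows.append(row)
    return pd.DataFrame(rows), results


# --------------------------------------------------------------------------
# duct + uniform screen fixture (solver/oracle workbench)


class UniformScreenCell:
    """Synthetic braid cell with prescribed porosity and hydraulic diameter."""

    def __init__(self, eps: float, D_h: float):
        self.porosity = eps
        self.hydraulic_diameter = D_h
        self.arc_position = 0.0
        self.angle = 0.0


def build_duct_screen_case(
    eps: float,
    D_h: float,
    mean_velocity: float,
    fluid: FluidProperties,
    height: float = 2.0e-3,
    length: float = 16e-3,
    cell_size: float = 1.0e-4,
    t_shell: float = 60e-6,
    x_screen: float | None = None,
    slip_walls: bool = True,
):
    """Plain duct with a uniform transverse screen of the given (eps, D_h)."""
    nx = int(round(length / cell_size))
    ny = int(round(height / cell_size))
    grid = StructuredGrid(nx, ny, length / nx, height / ny)
    xs = x_screen if x_screen is not None else length / 2
    grid.mark_shell(axis=0, position=xs, t_shell=t_shell, normal=(1.0, 0.0))
    porous = build_porous_field([UniformScreenCell(eps, D_h)], grid, t_shell, fluid)
    wall = "slip" if slip_walls else "noslip"
    bc = BoundaryConditions(
        mass_flow=fluid.density * mean_velocity * height, wall_y0=wall, wall_y1=wall
    )
    return grid, porous, bc


def duct_screen_pressure_jump(
    eps: float, D_h: float, mean_velocity: float, fluid: FluidProperties,
    cell_size: float = 1.0e-4, tol: float = 1e-6, **kw,
) -> float:
    """Solve the duct+screen case and measure the pressure jump (Pa)."""
    grid, porous, bc = build_duct_screen_case(
        eps, D_h, mean_velocity, fluid, cell_size=cell_size, **kw
    )
    flow = solve_steady(grid, porous, fluid, bc, tol=tol, max_iter=4000)
    if not flow.converged:
        raise WorkbenchError("duct+screen solve did not converge")
    L = grid.nx * grid.dx
    return pressure_drop(flow, 0.25 * L, 0.75 * L)
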