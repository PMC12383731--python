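"""Hemodynamic parameters of an aneurysm flow field and change-rate reports.

Four scalar metrics summarize the intrasaccular flow: the mean velocity over
the sac, the mean shear rate at sac-wall-adjacent cells, the inflow rate
across the neck plane (inward-directed component only), and the theoretical
turnover time, i.e. sac volume divided by inflow rate.  Treatment scenarios
are compared with the relative change

    X_RE = (X_variant - X_baseline) / X_baseline * 100  [%]

the same formula used to validate the porous model against the
wire-resolved reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowsolve import REGION_SAC, FlowField, StructuredGrid

__all__ = ["HemoMetrics", "ComparisonReport", "compute_metrics", "change_rate"]

METRIC_NAMES = ("mean_velocity", "mean_shear_rate", "inflow_rate", "turnover_time")


class MetricsError(ValueError):
    pass


@dataclass
class HemoMetrics:
    """The four sac metrics plus the sac volume they were computed from.

    ``turnover_time`` is NaN when the inflow rate is numerically zero (no
    flow enters the sac, turnover is undefined).  When defined,
    ``turnover_time * inflow_rate == sac_volume`` to 1e-10 relative.
    """

    mean_velocity: float
    mean_shear_rate: float
    inflow_rate: float
    turnover_time: float
    sac_volume: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_velocity": self.mean_velocity,
            "mean_shear_rate": self.mean_shear_rate,
            "inflow_rate": self.inflow_rate,
            "turnover_time": self.turnover_time,
            "sac_volume": self.sac_volume,
        }


def _wall_adjacent_shear(grid: StructuredGrid, flow: FlowField, cells: np.ndarray) -> float:
    """Mean strain-rate magnitude sqrt(2 D:D) at the given cells.

    Gradients are one-sided toward stair-step walls: a solid neighbor
    contributes the no-slip value at the wall face, half a spacing away.
    """
    fluidm = grid.fluid_mask()
    ii, jj = np.nonzero(cells)
    vals = np.empty(ii.size)
    u, v = flow.u, flow.v
    dx, dy = grid.dx, grid.dy
    nx, ny = grid.nx, grid.ny

    def d_dq(f, i, j, axis):
        h = dx if axis == 0 else dy
        di, dj = (1, 0) if axis == 0 else (0, 1)
        # sample values and distances on each side (wall face at h/2)
        ip, jp = i + di, j + dj
        im, jm = i - di, j - dj
        if 0 <= ip < nx and 0 <= jp < ny and fluidm[ip, jp]:
            fp, hp = f[ip, jp], h
        else:
            fp, hp = 0.0, h / 2
        if 0 <= im < nx and 0 <= jm < ny and fluidm[im, jm]:
            fm, hm = f[im, jm], h
        else:
            fm, hm = 0.0, h / 2
        return (fp - fm) / (hp + hm)

    for k in range(ii.size):
        i, j = int(ii[k]), int(jj[k])
        dudx = d_dq(u, i, j, 0)
        dudy = d_dq(u, i, j, 1)
        dvdx = d_dq(v, i, j, 0)
        dvdy = d_dq(v, i, j, 1)
        dxy = 0.5 * (dudy + dvdx)
        vals[k] = np.sqrt(2 * (dudx**2 + dvdy**2 + 2 * dxy**2))
    return float(vals.mean()) if vals.size else 0.0


def compute_metrics(
    flow: FlowField,
    grid: StructuredGrid | None = None,
    neck_faces: list[tuple[int, int, int]] | None = None,
    sac_mask: np.ndarray | None = None,
) -> HemoMetrics:
    """Evaluate the four sac metrics on a converged flow field.

    ``neck_faces`` are (i, j_face, sign) y-normal faces whose positive
    ``sign`` direction points into the sac; inflow counts only the
    inward-directed normal component.  Defaults are taken from the grid's
    region tags and recorded neck-face list.
    """
    grid = grid or flow.grid
    if sac_mask is None:
        sac_mask = grid.region == REGION_SAC
    sac_mask = np.asarray(sac_mask, dtype=bool) & grid.fluid_mask()
    if not sac_mask.any():
        raise MetricsError("empty aneurysm sac")
    neck_faces = neck_faces if neck_faces is not None else grid.neck_faces
    V = grid.volumes()
    v_sac = float(np.sum(V[sac_mask]))

    speed = flow.speed()
    mean_v = float(np.sum(speed[sac_mask] * V[sac_mask]) / v_sac)

    # sac cells touching a solid cell (or the domain boundary beyond the sac)
    solid = ~grid.fluid_mask()
    pad = np.pad(solid, 1, constant_values=True)
    touches_wall = (
        pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    ) & sac_mask
    if not touches_wall.any():
        touches_wall = sac_mask
    shear = _wall_adjacent_shear(grid, flow, touches_wall)

    Ay = grid.face_area_y()
    inflow = 0.0
    for i, jf, sign in neck_faces:
        q = sign * flow.vf[i, jf] * Ay[jf]
        if q > 0:
            inflow += q
    if grid.axisymmetric:
        inflow *= 2 * np.pi
        v_sac *= 2 * np.pi
    turnover = v_sac / inflow if inflow > 1e-15 else float("nan")
    return HemoMetrics(
        mean_velocity=mean_v,
        mean_shear_rate=shear,
        inflow_rate=float(inflow),
        turnover_time=turnover,
        sac_volume=v_sac,
    )


def change_rate(x_variant: float, x_baseline: float, decimals: int | None = 1) -> float:
    """Relative change (%) of a variant against a baseline, Eq-style.

    Reported to one decimal by default (pass ``decimals=None`` for the raw
    value); raises on a zero baseline.
    """
    if x_baseline == 0:
        raise MetricsError("change rate undefined for zero baseline")
    val = 100.0 * (x_variant - x_baseline) / x_baseline
    return float(val) if decimals is None else float(round(val, decimals))


@dataclass
class ComparisonReport:
    """Per-metric relative changes of a variant flow against a baseline.

    The change rate is only antisymmetric under swapping baseline and
    variant to first order; the report stores the orientation labels so the
    sign convention stays unambiguous.
    """

    baseline_label: str
    variant_label: str
    baseline: dict[str, float]
    variant: dict[str, float]

    def relative_errors(self, decimals: int | None = 1) -> dict[str, float]:
        out = {}
        for k, xb in self.baseline.items():
            xv = self.variant.get(k)
            if xv is None or xb == 0 or not np.isfinite(xb) or not np.isfinite(xv):
                continue
            out[k] = change_rate(xv, xb, decimals=decimals)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        err = self.relative_errors()
        for k in self.baseline:
            rows.append(
                {
                    "metric": k,
                    self.baseline_label: self.baseline[k],
                    self.variant_label: self.variant.get(k, np.nan),
                    "change_rate_pct": err.get(k, np.nan),
                }
            )
        return pd.DataFrame(rows)
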