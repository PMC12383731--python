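"""Minimal legacy-ASCII VTK writers for structured fields and wire polylines."""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_vtk", "write_polylines_vtk"]


def write_structured_vtk(path, grid, cell_data: dict[str, np.ndarray]) -> None:
    """Write cell-centered arrays on a uniform 2D grid as STRUCTURED_POINTS.

    Vector-valued entries must have a trailing dimension of 2 (padded to 3).
    """
    nx, ny = grid.nx, grid.ny
    lines = [
        "# vtk DataFile Version 3.0",
        "stentflow field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        f"ORIGIN {grid.x0} {grid.y0} 0",
        f"SPACING {grid.dx} {grid.dy} 1",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in cell_data.items():
        a = np.asarray(arr)
        if a.ndim == 3 and a.shape[2] == 2:
            lines.append(f"VECTORS {name} float")
            flat = a.transpose(1, 0, 2).reshape(-1, 2)  # x fastest
            lines.extend(f"{x:.8g} {y:.8g} 0" for x, y in flat)
        else:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.8g}" for v in a.T.ravel())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_polylines_vtk(path, polylines: list[np.ndarray]) -> None:
    """Write 3D polylines (e.g. stent wire paths) as legacy POLYDATA."""
    pts = np.concatenate(polylines, axis=0)
    lines = [
        "# vtk DataFile Version 3.0",
        "stentflow wires",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(pts)} float",
    ]
    lines.extend(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pts)
    total = sum(len(p) + 1 for p in polylines)
    lines.append(f"LINES {len(polylines)} {total}")
    off = 0
    for p in polylines:
        lines.append(" ".join(map(str, [len(p), *range(off, off + len(p))])))
        off += len(p)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
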