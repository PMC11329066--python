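"""Minimal legacy-ASCII VTK writers for lattice scalar fields and polylines."""

from __future__ import annotations

import numpy as np


def write_structured_scalars(path, fields: dict[str, np.ndarray], spacing: float,
                             origin=(0.0, 0.0)) -> None:
    """Write named 2D scalar fields as a VTK structured-points dataset."""
    first = next(iter(fields.values()))
    ny, nx = first.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlattice scalars\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} 0\n")
        fh.write(f"SPACING {spacing} {spacing} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            if arr.shape != (ny, nx):
                raise ValueError(f"field {name!r} has mismatched shape")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt="%.6g")


def write_polylines(path, polylines: list[np.ndarray]) -> None:
    """Write 2D polylines (e.g. rotor trajectories) as VTK polydata."""
    pts = [np.asarray(p, dtype=float) for p in polylines]
    n_pts = sum(p.shape[0] for p in pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntrajectories\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n")
        for p in pts:
            for x, y in p:
                fh.write(f"{x:.6g} {y:.6g} 0\n")
        size = sum(p.shape[0] + 1 for p in pts)
        fh.write(f"LINES {len(pts)} {size}\n")
        offset = 0
        for p in pts:
            ids = " ".join(str(offset + i) for i in range(p.shape[0]))
            fh.write(f"{p.shape[0]} {ids}\n")
            offset += p.shape[0]
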