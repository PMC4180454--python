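"""Plain-text mesh serialization: legacy VTK polydata and PLY.

The legacy VTK ASCII polydata format is written directly (it is a simple
text format); PLY goes through trimesh.  Point data arrays (scalars or
3-vectors) can be attached to VTK output for visualization of q-value maps
and growth fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk_polydata(path, points, faces, point_data: dict | None = None) -> None:
    """Write triangles + per-point scalars/vectors as legacy VTK ASCII."""
    points = np.asarray(points, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "lvshape surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
    ]
    lines += [" ".join(f"{x:.8g}" for x in p) for p in points]
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines += ["3 " + " ".join(str(i) for i in f) for f in faces]
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.8g}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{x:.8g}" for x in v) for v in arr]
            else:
                raise ValueError(f"point data {name!r} must be (n,) or (n, 3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Read back a legacy VTK ASCII polydata file written by this module."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    points = faces = None
    point_data: dict[str, np.ndarray] = {}
    line = next(it)
    while True:
        try:
            if line.startswith("POINTS"):
                n = int(line.split()[1])
                points = np.array(
                    [[float(x) for x in next(it).split()] for _ in range(n)]
                )
            elif line.startswith("POLYGONS"):
                n = int(line.split()[1])
                faces = np.array(
                    [[int(x) for x in next(it).split()[1:]] for _ in range(n)]
                )
            elif line.startswith("SCALARS"):
                name = line.split()[1]
                next(it)  # LOOKUP_TABLE
                point_data[name] = np.array(
                    [float(next(it)) for _ in range(len(points))]
                )
            elif line.startswith("VECTORS"):
                name = line.split()[1]
                point_data[name] = np.array(
                    [[float(x) for x in next(it).split()] for _ in range(len(points))]
                )
            line = next(it)
        except StopIteration:
            break
    return points, faces, point_data


def write_ply(path, points, faces) -> None:
    """Write a triangle mesh as ASCII PLY via trimesh."""
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=np.asarray(points, dtype=float),
        faces=np.asarray(faces, dtype=int),
        process=False,
    )
    mesh.export(str(path), file_type="ply", encoding="ascii")


def read_ply(path):
    import trimesh

    mesh = trimesh.load(str(path), file_type="ply", process=False)
    return np.asarray(mesh.vertices), np.asarray(mesh.faces)
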