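"""Export helpers: legacy VTK text, STL surfaces, CSV/JSON reports.

The VTK writers emit the plain-text legacy format (readable by ParaView and
friends) — structured points for voxel indicator fields, unstructured grids
for solved meshes with nodal displacements and element stresses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "write_vtk_image",
    "write_vtk_mesh",
    "write_stl",
    "write_manifest",
]


def write_vtk_image(path, fields: dict, spacing) -> None:
    """Write 3D cell-data fields on a regular grid as legacy VTK structured points."""
    fields = {k: np.asarray(v) for k, v in fields.items()}
    shape = next(iter(fields.values())).shape
    if np.isscalar(spacing):
        spacing = (spacing,) * 3
    lines = [
        "# vtk DataFile Version 3.0",
        "stiffmatch voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {shape[0] + 1} {shape[1] + 1} {shape[2] + 1}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}",
        f"CELL_DATA {int(np.prod(shape))}",
    ]
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6g}" for v in arr.ravel(order="F"))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_mesh(path, mesh, point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Write a solved VoxelMesh as a legacy VTK unstructured grid.

    Reported element quantities are element-centroid values.
    """
    pts = mesh.coords
    conn = mesh.conn
    out = [
        "# vtk DataFile Version 3.0",
        "stiffmatch hexahedral mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    out.extend(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in pts)
    out.append(f"CELLS {len(conn)} {9 * len(conn)}")
    out.extend("8 " + " ".join(str(i) for i in c) for c in conn)
    out.append(f"CELL_TYPES {len(conn)}")
    out.extend("12" for _ in range(len(conn)))  # VTK_HEXAHEDRON
    if point_data:
        out.append(f"POINT_DATA {len(pts)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} float")
                out.extend(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in arr)
            else:
                out.append(f"SCALARS {name} float 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.6g}" for v in arr)
    if cell_data:
        out.append(f"CELL_DATA {len(conn)}")
        for name, arr in cell_data.items():
            out.append(f"SCALARS {name} float 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.6g}" for v in np.asarray(arr))
    Path(path).write_text("\n".join(out) + "\n")


def write_stl(path, solid: np.ndarray, spacing) -> None:
    """Export the surface of a voxel indicator field as STL (marching cubes)."""
    import trimesh

    if np.isscalar(spacing):
        spacing = (spacing,) * 3
    m = trimesh.voxel.ops.matrix_to_marching_cubes(np.asarray(solid, bool))
    m.apply_scale(spacing)
    m.export(str(path))


def write_manifest(outdir, config: dict) -> Path:
    """Echo the fully resolved run configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(config, indent=2, default=str) + "\n")
    return path
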