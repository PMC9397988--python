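"""Mesh and field export/import: ascii VTU and Gmsh MSH v2.2.

Small self-contained writers/readers for the two standard unstructured-mesh
containers the package exchanges: VTK XML UnstructuredGrid (quadratic
triangle, VTK cell type 22) for meshes plus nodal/cell fields, and Gmsh MSH
2.2 (element type 9) for labeled meshes. Region labels are stored as an
integer cell array named ``region_id`` with a JSON sidecar label map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .phantom import LabeledMesh
from .regions import label_map

__all__ = ["write_vtu", "write_msh", "read_msh", "write_label_map"]

_VTK_TRIANGLE6 = 22
_GMSH_TRIANGLE6 = 9


def _fmt(arr: np.ndarray, per_row: int = 6) -> str:
    flat = np.asarray(arr).ravel()
    lines = []
    for i in range(0, len(flat), per_row):
        chunk = flat[i:i + per_row]
        if np.issubdtype(chunk.dtype, np.integer):
            lines.append(" ".join(str(int(v)) for v in chunk))
        else:
            lines.append(" ".join(f"{v:.10g}" for v in chunk))
    return "\n".join(lines)


def write_vtu(path, mesh: LabeledMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (+ optional fields) as an ascii .vtu file.

    ``region_id`` is always included as cell data; 2D vectors/tensors are
    written with their natural component count.
    """
    path = Path(path)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region_id", mesh.region_id)
    point_data = dict(point_data or {})
    n_pts, n_cells = mesh.n_nodes, mesh.n_elems

    def data_arrays(data: dict[str, np.ndarray], n: int) -> str:
        parts = []
        for name, arr in data.items():
            arr = np.asarray(arr)
            if len(arr) != n:
                raise ValueError(f"field {name!r} has length {len(arr)} != {n}")
            comps = 1 if arr.ndim == 1 else arr.shape[1]
            typ = ("Int32" if np.issubdtype(arr.dtype, np.integer)
                   else "Float64")
            parts.append(
                f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{comps}" format="ascii">\n'
                f"{_fmt(arr)}\n</DataArray>")
        return "\n".join(parts)

    pts3 = np.column_stack([mesh.points, np.zeros(n_pts)])
    offsets = 6 * np.arange(1, n_cells + 1)
    types = np.full(n_cells, _VTK_TRIANGLE6)
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">
<Points>
<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">
{_fmt(pts3)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_fmt(mesh.tris)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_fmt(offsets)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_fmt(types)}
</DataArray>
</Cells>
<PointData>
{data_arrays(point_data, n_pts)}
</PointData>
<CellData>
{data_arrays(cell_data, n_cells)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)


def write_label_map(path) -> None:
    Path(path).write_text(json.dumps(label_map(), indent=2) + "\n")


def write_msh(path, mesh: LabeledMesh) -> None:
    """Write a labeled mesh as Gmsh MSH v2.2 ascii (region id = physical tag)."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_nodes)]
    for i, (x, y) in enumerate(mesh.points, start=1):
        lines.append(f"{i} {x:.10g} {y:.10g} 0")
    lines += ["$EndNodes", "$Elements", str(mesh.n_elems)]
    for e, (tri, rid) in enumerate(zip(mesh.tris, mesh.region_id), start=1):
        conn = " ".join(str(n + 1) for n in tri)
        lines.append(f"{e} {_GMSH_TRIANGLE6} 2 {rid} {rid} {conn}")
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))


def read_msh(path) -> LabeledMesh:
    """Read a Gmsh MSH v2.2 ascii file with quadratic-triangle elements.

    The first element tag is taken as the region id. Boundary sets are not
    reconstructed (user-supplied meshes define their own scene assembly).
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"malformed MSH file: missing {tag}")

    until("$Nodes")
    n_nodes = int(next(it))
    pts = np.empty((n_nodes, 2))
    for k in range(n_nodes):
        parts = next(it).split()
        pts[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
    until("$Elements")
    n_el = int(next(it))
    tris, rids = [], []
    for _ in range(n_el):
        parts = next(it).split()
        etype = int(parts[1])
        if etype != _GMSH_TRIANGLE6:
            continue
        n_tags = int(parts[2])
        rids.append(int(parts[3]) if n_tags else 0)
        conn = [int(v) - 1 for v in parts[3 + n_tags:3 + n_tags + 6]]
        tris.append(conn)
    if not tris:
        raise ValueError("no quadratic-triangle elements in MSH file")
    return LabeledMesh(points=pts, tris=np.asarray(tris, dtype=np.int64),
                       region_id=np.asarray(rids, dtype=np.int64))
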