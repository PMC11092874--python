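"""Plain-text artifact formats: CSV fields, JSON-lines histories, ASCII VTU."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import StrainField
from .mesh import TriMesh

__all__ = [
    "write_solution_csv",
    "read_strain_csv",
    "write_nodal_csv",
    "write_element_csv",
    "read_element_csv",
    "write_history_jsonl",
    "write_vtu",
]


def write_solution_csv(path, strains: StrainField, u: np.ndarray | None = None):
    """One row per node: ``x,y[,ux,uy],exx,eyy,exy``."""
    cols = [strains.points[:, 0], strains.points[:, 1]]
    header = ["x", "y"]
    if u is not None:
        cols += [u[:, 0], u[:, 1]]
        header += ["ux", "uy"]
    cols += [strains.exx, strains.eyy, strains.exy]
    header += ["exx", "eyy", "exy"]
    np.savetxt(
        path,
        np.column_stack(cols),
        delimiter=",",
        header=",".join(header),
        comments="",
    )


def read_strain_csv(path) -> StrainField:
    """Read columnar strain data; displacement columns, if present, are skipped."""
    with open(path) as fh:
        names = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    idx = {name: i for i, name in enumerate(names)}
    for req in ("x", "y", "exx", "eyy", "exy"):
        if req not in idx:
            raise ValueError(f"missing column {req!r} in {path}")
    return StrainField(
        points=data[:, [idx["x"], idx["y"]]],
        exx=data[:, idx["exx"]],
        eyy=data[:, idx["eyy"]],
        exy=data[:, idx["exy"]],
    )


def write_nodal_csv(path, points: np.ndarray, values: np.ndarray):
    np.savetxt(
        path,
        np.column_stack([points, values]),
        delimiter=",",
        header="x,y,value",
        comments="",
    )


def write_element_csv(path, values: np.ndarray):
    np.savetxt(
        path,
        np.column_stack([np.arange(len(values)), values]),
        delimiter=",",
        header="element_id,value",
        comments="",
        fmt=["%d", "%.17g"],
    )


def read_element_csv(path) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data[:, 1]


def write_history_jsonl(path, history: list):
    with open(path, "w") as fh:
        for rec in history:
            fh.write(json.dumps(rec) + "\n")


def write_vtu(
    path,
    mesh: TriMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
):
    """Minimal ASCII VTK unstructured-grid writer (triangle cells only)."""

    def _array(name, values, components=1):
        flat = np.asarray(values, dtype=float).reshape(len(values), -1)
        body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in flat)
        return (
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{components}" format="ascii">\n{body}\n</DataArray>'
        )

    points3 = np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)])
    conn = " ".join(map(str, mesh.elements.ravel()))
    offsets = " ".join(map(str, np.arange(1, mesh.n_elements + 1) * 3))
    types = " ".join(["5"] * mesh.n_elements)  # VTK_TRIANGLE
    pd = "\n".join(
        _array(k, v, components=(np.asarray(v).ndim > 1 and np.asarray(v).shape[1]) or 1)
        for k, v in (point_data or {}).items()
    )
    cd = "\n".join(_array(k, v) for k, v in (cell_data or {}).items())
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">
<Points>
{_array("points", points3, 3)}
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{offsets}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{types}
</DataArray>
</Cells>
<PointData>
{pd}
</PointData>
<CellData>
{cd}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)
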