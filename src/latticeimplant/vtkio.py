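"""Minimal legacy-ASCII VTK I/O for hexahedral unstructured grids.

Covers exactly what this package emits and re-reads: POINTS, CELLS of
VTK_HEXAHEDRON (type 12), CELL_DATA / POINT_DATA scalar and vector arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fe_solver import MacroMesh

_HEX_TYPE = 12


def write_vtk(
    path: str | Path,
    mesh: MacroMesh,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "latticeimplant grid",
) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes]
    ne = mesh.n_elements
    lines.append(f"CELLS {ne} {ne * 9}")
    lines += ["8 " + " ".join(map(str, el)) for el in mesh.elements]
    lines.append(f"CELL_TYPES {ne}")
    lines += [str(_HEX_TYPE)] * ne
    for section, data in (("CELL_DATA", cell_data), ("POINT_DATA", point_data)):
        if not data:
            continue
        count = ne if section == "CELL_DATA" else mesh.n_nodes
        lines.append(f"{section} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.10g}" for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> tuple[MacroMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read a grid written by :func:`write_vtk` (legacy ASCII, hexes only)."""
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    i = 0

    def line() -> str:
        nonlocal i
        out = tokens[i]
        i += 1
        return out

    header = [line() for _ in range(4)]
    if "UNSTRUCTURED_GRID" not in header[3]:
        raise ValueError("only unstructured grids are supported")
    npts = int(line().split()[1])
    nodes = np.array([[float(v) for v in line().split()] for _ in range(npts)])
    ncells = int(line().split()[1])
    elements = []
    for _ in range(ncells):
        parts = line().split()
        if parts[0] != "8":
            raise ValueError("only 8-node hexahedra are supported")
        elements.append([int(v) for v in parts[1:]])
    line()  # CELL_TYPES header
    for _ in range(ncells):
        if line().strip() != str(_HEX_TYPE):
            raise ValueError("only VTK_HEXAHEDRON cells are supported")
    cell_data: dict[str, np.ndarray] = {}
    point_data: dict[str, np.ndarray] = {}
    current = None
    count = 0
    while i < len(tokens):
        t = line().strip()
        if not t:
            continue
        if t.startswith("CELL_DATA"):
            current, count = cell_data, int(t.split()[1])
        elif t.startswith("POINT_DATA"):
            current, count = point_data, int(t.split()[1])
        elif t.startswith("SCALARS"):
            name = t.split()[1]
            line()  # LOOKUP_TABLE
            current[name] = np.array([float(line()) for _ in range(count)])
        elif t.startswith("VECTORS"):
            name = t.split()[1]
            current[name] = np.array(
                [[float(v) for v in line().split()] for _ in range(count)]
            )
    mesh = MacroMesh(nodes=nodes, elements=np.array(elements, dtype=int))
    return mesh, cell_data, point_data
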