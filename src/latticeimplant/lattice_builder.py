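"""Map an optimized density field to graded lattice geometry and export it.

Each macro element becomes one unit cell: the wireframe of the chosen cell
type is mapped into the element by the trilinear transform of the unit cube
(macro elements are assumed roughly cubic; curved elements are approximated
by their trilinear image), the strut radius realizing the element's relative
density.  Coincident boundary nodes of adjacent cells are merged so the
graded lattice is a single connected strut network.

The printable surface is generated by voxelizing the strut network (which
performs the boolean union of all strut cylinders implicitly) and running
marching cubes; trimesh handles STL export and validity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._hex8 import XI_NODES, element_volumes
from .unit_cell import DesignWindow, UnitCellSpec, build_cell


class ManufacturabilityError(ValueError):
    def __init__(self, element_ids, t_min):
        self.element_ids = list(element_ids)
        super().__init__(
            f"{len(self.element_ids)} element(s) require struts thinner than "
            f"{t_min} mm: {self.element_ids[:10]}"
        )


class ExportError(RuntimeError):
    pass


@dataclass
class LatticeModel:
    """Instanced graded unit cells plus the merged strut network."""

    cells: list  # (element id, UnitCellSpec, (8, 3) corner coords)
    nodes: np.ndarray  # merged wireframe nodes, (N, 3) mm
    struts: np.ndarray  # (M, 2) int
    radii: np.ndarray  # per-strut radius, mm
    nominal_volume: float  # sum rho_e * V_e, mm^3
    mean_cell_edge: float
    surface: object | None = None  # trimesh.Trimesh, built lazily

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _trilinear_map(unit_pts: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Map points of the unit cube onto a hexahedron via its shape functions."""
    xi = 2.0 * unit_pts - 1.0
    w = np.ones((len(unit_pts), 8))
    for a in range(8):
        sx, sy, sz = XI_NODES[a]
        w[:, a] = 0.125 * (1 + sx * xi[:, 0]) * (1 + sy * xi[:, 1]) * (1 + sz * xi[:, 2])
    return w @ corners


def build(
    mesh,
    densities,
    cell_type: str = "octet",
    *,
    window: DesignWindow | None = None,
) -> LatticeModel:
    """Instance one sized unit cell per macro element and merge the network.

    ``densities`` is a per-element array or DensityField.  When a
    :class:`DesignWindow` is given, elements whose density would need struts
    thinner than the printable floor raise :class:`ManufacturabilityError`.
    """
    rho = np.asarray(getattr(densities, "rho", densities), dtype=float)
    if len(rho) != mesh.n_elements:
        raise ValueError("one density per macro element required")
    coords = mesh.element_coords()
    edges = element_volumes(coords) ** (1.0 / 3.0)  # effective cubic edge, mm

    # unit-cell wireframe shared by all elements of a type
    proto = build_cell(UnitCellSpec(cell_type=cell_type, l=1.0, rho=float(rho[0])))
    unit_nodes = proto.nodes
    unit_struts = proto.struts

    cells = []
    all_nodes = []
    all_struts = []
    all_radii = []
    bad = []
    offset = 0
    for e in range(mesh.n_elements):
        spec = UnitCellSpec(cell_type=cell_type, l=float(edges[e]), rho=float(rho[e]))
        if window is not None and 2.0 * spec.t < window.t_min - 1e-12:
            bad.append(e)
            continue
        mapped = _trilinear_map(unit_nodes, coords[e])
        cells.append((e, spec, coords[e]))
        all_nodes.append(mapped)
        all_struts.append(unit_struts + offset)
        all_radii.append(np.full(len(unit_struts), spec.t))
        offset += len(unit_nodes)
    if bad:
        raise ManufacturabilityError(bad, window.t_min)
    if not cells:
        raise ValueError("empty lattice: no cells built")

    nodes = np.vstack(all_nodes)
    struts = np.vstack(all_struts)
    radii = np.concatenate(all_radii)

    # merge coincident boundary nodes of adjacent cells
    mean_edge = float(edges.mean())
    tol = 1e-6 * mean_edge
    key = np.round(nodes / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged_nodes = nodes[first]
    struts = inverse[struts]

    # deduplicate struts shared by neighbouring cells, keeping the larger radius
    skey = np.sort(struts, axis=1)
    order = np.lexsort((-radii, skey[:, 1], skey[:, 0]))
    skey, struts, radii = skey[order], struts[order], radii[order]
    keep = np.ones(len(struts), dtype=bool)
    keep[1:] = np.any(skey[1:] != skey[:-1], axis=1)

    return LatticeModel(
        cells=cells,
        nodes=merged_nodes,
        struts=struts[keep],
        radii=radii[keep],
        nominal_volume=float((rho * element_volumes(coords)).sum()),
        mean_cell_edge=mean_edge,
    )


# ---------------------------------------------------------------------------
# voxel union and surface extraction


def voxelize_lattice(
    model: LatticeModel, *, voxels_per_cell: int = 12, pad: int = 2
) -> tuple[np.ndarray, np.ndarray, float]:
    """Boolean-union indicator grid of the strut network.

    Returns ``(grid, origin, spacing)``; the grid is padded with void so an
    isosurface is always closed.
    """
    h = model.mean_cell_edge / voxels_per_cell
    rmax = float(model.radii.max())
    lo = model.nodes.min(axis=0) - rmax - pad * h
    hi = model.nodes.max(axis=0) + rmax + pad * h
    dims = np.ceil((hi - lo) / h).astype(int) + 1
    grid = np.zeros(dims, dtype=bool)
    axes = [lo[d] + (np.arange(dims[d]) + 0.5) * h for d in range(3)]
    for (ia, ib), r in zip(model.struts, model.radii):
        a, b = model.nodes[ia], model.nodes[ib]
        slo = np.minimum(a, b) - r - h
        shi = np.maximum(a, b) + r + h
        i0 = np.maximum(((slo - lo) / h).astype(int), 0)
        i1 = np.minimum(((shi - lo) / h).astype(int) + 1, dims)
        if np.any(i0 >= i1):
            continue
        X, Y, Z = np.meshgrid(
            axes[0][i0[0] : i1[0]],
            axes[1][i0[1] : i1[1]],
            axes[2][i0[2] : i1[2]],
            indexing="ij",
        )
        P = np.stack([X, Y, Z], axis=-1)
        u = b - a
        uu = float(u @ u)
        d = P - a
        if uu < 1e-30:
            dist2 = np.einsum("...i,...i", d, d)
        else:
            s = np.clip(np.einsum("...i,i", d, u) / uu, 0.0, 1.0)
            closest = d - s[..., None] * u
            dist2 = np.einsum("...i,...i", closest, closest)
        grid[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= dist2 <= r * r
    return grid, lo, h


def solid_volume(model: LatticeModel, *, voxels_per_cell: int = 12) -> float:
    """Union solid volume of the strut network, mm^3 (voxel counting)."""
    grid, _, h = voxelize_lattice(model, voxels_per_cell=voxels_per_cell)
    return float(grid.sum()) * h**3


def build_surface(model: LatticeModel, *, voxels_per_cell: int = 12):
    """Triangulated union surface of the lattice via marching cubes."""
    import trimesh
    from skimage import measure

    grid, lo, h = voxelize_lattice(model, voxels_per_cell=voxels_per_cell)
    if not grid.any():
        raise ExportError("empty model: no solid voxels")
    verts, faces, _, _ = measure.marching_cubes(grid.astype(np.float32), level=0.5, spacing=(h, h, h))
    verts = verts + lo + 0.5 * h
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:  # marching cubes may orient inward
        mesh.invert()
    model.surface = mesh
    return mesh


def export_stl(model: LatticeModel, path: str | Path, *, voxels_per_cell: int = 12) -> None:
    """Write a watertight STL of the lattice surface.

    Every connected component must be closed and consistently oriented;
    otherwise the export aborts naming the broken faces.
    """
    mesh = model.surface if model.surface is not None else build_surface(model, voxels_per_cell=voxels_per_cell)
    if len(mesh.faces) == 0:
        raise ExportError("empty model: nothing to export")
    if not mesh.is_watertight or not mesh.is_winding_consistent:
        import trimesh

        broken = trimesh.repair.broken_faces(mesh)
        raise ExportError(f"non-manifold triangulation; offending facets: {broken[:20]}")
    mesh.export(str(path))


def export_wireframe(model: LatticeModel, nodes_path: str | Path, struts_path: str | Path) -> None:
    """Write the merged strut network as two CSVs (nodes; struts with radii)."""
    np.savetxt(nodes_path, model.nodes, delimiter=",", header="x_mm,y_mm,z_mm", comments="")
    with open(struts_path, "w") as fh:
        fh.write("node_a,node_b,radius_mm\n")
        for (a, b), r in zip(model.struts, model.radii):
            fh.write(f"{a},{b},{r}\n")
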