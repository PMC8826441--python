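"""Deterministic synthetic stand-ins for the study geometry and imaging data.

Three generators cover every stage of the pipeline without any downloads:

* a three-tissue CT phantom (nested spherical shells of cortical, cancellous
  and marrow HU levels in air) with recoverable ground-truth labels;
* a hemispherical-shell "cage" benchmark — a spherical dome patch with two
  flange strips, flange ends fixed, the hip-joint resultant spread over the
  socket region of the inner surface;
* a box cantilever, the standard compliance-minimization benchmark.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .bone_material import VoxelVolume
from .fe_solver import MacroMesh


def hip_resultant(mass_kg: float = 80.0, factor: float = 2.5, g: float = 9.81) -> float:
    """Hip-joint resultant force, N: ``factor`` x body weight (default 250%)."""
    return factor * mass_kg * g


#: Default hip-joint force components, N: the in-plane split of the 1962 N
#: resultant (250% of an 80 kg subject's weight).
DEFAULT_RESULTANT = (-408.0, 1919.0, 0.0)


@dataclass
class LoadCase:
    """A resultant force spread over a node set, plus the fixed node sets."""

    resultant: tuple[float, float, float] = DEFAULT_RESULTANT
    load_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fixed_node_sets: list = field(default_factory=list)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.resultant))

    def apply(self, mesh: MacroMesh) -> MacroMesh:
        """Return a mesh copy with this case's loads and constraints attached."""
        out = MacroMesh(
            nodes=mesh.nodes.copy(),
            elements=mesh.elements.copy(),
            fixed_dofs=[],
            loads=[],
        )
        for nodes in self.fixed_node_sets:
            for n in np.asarray(nodes, dtype=int):
                for d in range(3):
                    out.fixed_dofs.append((int(n), d))
        out.loads = distribute_load(out, self.load_nodes, np.asarray(self.resultant))
        return out


def _quad_area(p: np.ndarray) -> float:
    # two-triangle split of a (possibly warped) quad
    a1 = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[3] - p[0]))
    a2 = 0.5 * np.linalg.norm(np.cross(p[1] - p[2], p[3] - p[2]))
    return float(a1 + a2)


def distribute_load(mesh: MacroMesh, nodes, resultant) -> list:
    """Split a resultant over a node set proportionally to tributary area.

    Each boundary face contributes a quarter of its area to each of its nodes
    that belongs to the set; when the set touches no boundary face the split
    falls back to equal weights.  Returns ``(node, direction, magnitude)``
    triples whose vector sum is exactly the resultant.
    """
    nodes = np.asarray(nodes, dtype=int)
    resultant = np.asarray(resultant, dtype=float)
    if nodes.size == 0:
        return []
    node_set = set(nodes.tolist())
    weights = dict.fromkeys(nodes.tolist(), 0.0)
    for face in mesh.boundary_faces():
        members = [n for n in face.tolist() if n in node_set]
        if not members:
            continue
        quarter = _quad_area(mesh.nodes[face]) / 4.0
        for n in members:
            weights[n] += quarter
    w = np.array([weights[n] for n in nodes.tolist()])
    if w.sum() <= 0:
        w = np.ones(len(nodes))
    w = w / w.sum()
    loads = []
    for n, wi in zip(nodes.tolist(), w):
        for d in range(3):
            if resultant[d] != 0.0:
                loads.append((int(n), d, float(wi * resultant[d])))
    return loads


# ---------------------------------------------------------------------------
# CT phantom


@dataclass
class PhantomSpec:
    """Nested-shell CT phantom: marrow core, cancellous shell, cortical shell, air."""

    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    hu_levels: dict = field(
        default_factory=lambda: {
            "cortical": 1800.0,
            "cancellous": 600.0,
            "marrow": 50.0,
            "air": -1000.0,
        }
    )
    radii_fractions: tuple[float, float, float] = (0.22, 0.35, 0.45)
    noise_hu: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError("degenerate phantom dimensions")
        r1, r2, r3 = self.radii_fractions
        if not 0 < r1 < r2 < r3 <= 0.5:
            raise ValueError("radii fractions must be increasing and at most 0.5")


def _phantom_radius_grid(spec: PhantomSpec) -> np.ndarray:
    dims = np.array(spec.shape)
    sp = np.array(spec.spacing)
    axes = [(np.arange(dims[d]) + 0.5) * sp[d] for d in range(3)]
    center = dims * sp / 2.0
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)


def phantom_ground_truth(spec: PhantomSpec) -> np.ndarray:
    """Generative region label per voxel: marrow / cancellous / cortical / air."""
    R = _phantom_radius_grid(spec)
    extent = min(np.array(spec.shape) * np.array(spec.spacing))
    r1, r2, r3 = (f * extent for f in spec.radii_fractions)
    labels = np.full(spec.shape, "air", dtype=object)
    labels[R < r3] = "cortical"
    labels[R < r2] = "cancellous"
    labels[R < r1] = "marrow"
    return labels.astype(str)


def make_phantom(spec: PhantomSpec | None = None) -> VoxelVolume:
    """Synthetic HU volume covering all three bone branches, plus air outside."""
    if spec is None:
        spec = PhantomSpec()
    labels = phantom_ground_truth(spec)
    values = np.empty(spec.shape)
    for name, level in spec.hu_levels.items():
        values[labels == name] = level
    rng = np.random.default_rng(spec.seed)
    if spec.noise_hu > 0:
        values = values + rng.normal(0.0, spec.noise_hu, size=spec.shape)
    return VoxelVolume(values=values, spacing=np.array(spec.spacing))


# ---------------------------------------------------------------------------
# box cantilever


def _box_grid(nx: int, ny: int, nz: int, h: float) -> tuple[np.ndarray, np.ndarray]:
    gx, gy, gz = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * h

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return nodes, np.array(elems, dtype=int)


def make_cantilever(
    nx: int,
    ny: int,
    nz: int,
    *,
    elem_size: float = 1.35,
    total_load: float | None = None,
    load_at: str = "edge",
) -> tuple[MacroMesh, LoadCase]:
    """Cantilever beam of ``nx*ny*nz`` cube elements.

    The ``x = 0`` face is fully fixed.  ``load_at='edge'`` pulls the far top
    edge downward (-y); ``'center'`` loads the single centre node of the far
    face, which keeps the model mirror-symmetric for symmetry checks.  The
    default total load is the hip-joint resultant magnitude.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("dims must be >= 1")
    if total_load is None:
        total_load = hip_resultant()
    nodes, elems = _box_grid(nx, ny, nz, elem_size)
    mesh = MacroMesh(nodes=nodes, elements=elems)

    fixed = np.flatnonzero(np.abs(nodes[:, 0]) < 1e-12)
    if load_at == "edge":
        sel = (np.abs(nodes[:, 0] - nx * elem_size) < 1e-12) & (
            np.abs(nodes[:, 1] - ny * elem_size) < 1e-12
        )
        load_nodes = np.flatnonzero(sel)
    elif load_at == "center":
        target = np.array([nx * elem_size, ny * elem_size / 2.0, nz * elem_size / 2.0])
        load_nodes = np.array([int(np.argmin(np.linalg.norm(nodes - target, axis=1)))])
    else:
        raise ValueError(f"unknown load placement {load_at!r}")
    case = LoadCase(
        resultant=(0.0, -float(total_load), 0.0),
        load_nodes=load_nodes,
        fixed_node_sets=[fixed],
    )
    return case.apply(mesh), case


# ---------------------------------------------------------------------------
# hemispherical cage benchmark


def make_cage_benchmark(
    refinement: int = 1,
    *,
    outer_radius: float = 28.0,  # mm, acetabular-cage scale
    thickness: float = 3.0,  # mm shell thickness
    patch_half_width: float = 0.8,
    flange_rows: int | None = None,
    radii: np.ndarray | None = None,
) -> tuple[MacroMesh, LoadCase]:
    """Hemispherical shell with two flange strips — the implant analog.

    A gnomonic square patch is projected onto a sphere (apex along +y) and
    extruded radially into ``2*refinement`` hex layers; two flange strips
    continue the patch toward the equator on opposite sides (the iliac and
    ischial flange analogs).  Flange end rows are fully fixed and the
    hip-joint resultant is spread over the socket region of the inner
    surface by tributary area.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    m = 8 * refinement  # dome cells per side
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        outer_radius = float(radii[-1])
        nr = len(radii) - 1
    else:
        nr = 2 * refinement  # radial layers
    if flange_rows is None:
        flange_rows = 3 * refinement
    s = patch_half_width
    du = 2.0 * s / m
    R_in = outer_radius - thickness

    # parameter-plane vertex lattice: dome square plus two flange strips
    u_vals = np.arange(m + 1) * du - s
    v_dome = np.arange(m + 1) * du - s
    third = m // 3
    flange_cols = np.arange(third, m - third + 1)  # central band of u columns

    vkey_to_row = {}
    verts_uv = []  # (u index, v float)

    def add_row(v: float, cols: np.ndarray) -> None:
        for iu in cols:
            vkey_to_row.setdefault((int(iu), round(v, 9)), len(verts_uv))
            if vkey_to_row[(int(iu), round(v, 9))] == len(verts_uv):
                verts_uv.append((int(iu), float(v)))

    all_cols = np.arange(m + 1)
    for v in v_dome:
        add_row(float(v), all_cols)
    for k in range(1, flange_rows + 1):
        add_row(float(-s - k * du), flange_cols)
        add_row(float(s + k * du), flange_cols)

    # 3D nodes: radial layers from inside out
    if radii is None:
        radii = np.linspace(R_in, outer_radius, nr + 1)
    pts = []
    for iu, v in verts_uv:
        u = u_vals[iu]
        d = np.array([u, 1.0, v])
        d /= np.linalg.norm(d)
        pts.append(d)
    pts = np.array(pts)
    nodes = np.concatenate([pts * r for r in radii], axis=0)
    n_surf = len(pts)

    def nid(key, layer):
        return vkey_to_row[key] + layer * n_surf

    def quad_cells():
        cells = []
        # dome cells
        for iu in range(m):
            for iv in range(m):
                v0, v1 = round(float(v_dome[iv]), 9), round(float(v_dome[iv + 1]), 9)
                cells.append(((iu, v0), (iu + 1, v0), (iu + 1, v1), (iu, v1)))
        # flange cells (both sides)
        for k in range(flange_rows):
            v0, v1 = round(-s - k * du, 9), round(-s - (k + 1) * du, 9)
            for iu in flange_cols[:-1]:
                cells.append(((iu, v1), (iu + 1, v1), (iu + 1, v0), (iu, v0)))
            v0, v1 = round(s + k * du, 9), round(s + (k + 1) * du, 9)
            for iu in flange_cols[:-1]:
                cells.append(((iu, v0), (iu + 1, v0), (iu + 1, v1), (iu, v1)))
        return cells

    elems = []
    for cell in quad_cells():
        oriented = (cell[0], cell[3], cell[2], cell[1])  # right-handed with radial z
        for layer in range(nr):
            bottom = [nid(key, layer) for key in oriented]
            top = [nid(key, layer + 1) for key in oriented]
            elems.append(bottom + top)
    elems = np.array(elems, dtype=int)
    mesh = MacroMesh(nodes=nodes, elements=elems)

    # fix the outermost flange rows (all radial layers)
    v_end = {round(-s - flange_rows * du, 9), round(s + flange_rows * du, 9)}
    fixed = [
        nid((int(iu), v), layer)
        for (iu, vf) in verts_uv
        for v in [round(vf, 9)]
        if v in v_end
        for layer in range(nr + 1)
    ]
    # socket load nodes: inner surface near the apex
    socket = [
        vkey_to_row[(iu, round(vf, 9))]
        for (iu, vf) in verts_uv
        if abs(u_vals[iu]) <= 0.35 * s + 1e-9 and abs(vf) <= 0.35 * s + 1e-9
    ]
    case = LoadCase(
        resultant=DEFAULT_RESULTANT,
        load_nodes=np.array(sorted(socket), dtype=int),
        fixed_node_sets=[np.array(sorted(set(fixed)), dtype=int)],
    )
    return case.apply(mesh), case


@dataclass
class CageAssembly:
    """Cage shell bonded to a two-tissue bone backing (shared-node interfaces)."""

    mesh: MacroMesh
    case: LoadCase
    cage_mask: np.ndarray  # True for the lattice-cage elements
    bone_E: np.ndarray  # per-element modulus of the non-design elements, MPa
    bone_nu: np.ndarray
    interface_radius: float  # mm, cage-bone interface


def make_cage_assembly(
    refinement: int = 1,
    *,
    cage_inner: float = 25.0,
    cage_outer: float = 28.0,
    cancellous_outer: float = 31.0,
    cortical_outer: float = 34.0,
    cancellous_E: float = 600.0,
    cortical_E: float = 17000.0,
) -> CageAssembly:
    """Bonded synthetic assembly: lattice cage, cancellous shell, cortical shell.

    The cage occupies the innermost radial layers (the GA design region);
    the bone backing is fixed material.  Load transfer between the stiff
    implant and the compliant bone is what makes graded designs pay off, so
    this fixture exposes the stress-shielding comparisons.
    """
    nc = 2 * refinement
    nb = refinement
    radii = np.concatenate(
        [
            np.linspace(cage_inner, cage_outer, nc + 1),
            np.linspace(cage_outer, cancellous_outer, nb + 1)[1:],
            np.linspace(cancellous_outer, cortical_outer, nb + 1)[1:],
        ]
    )
    mesh, case = make_cage_benchmark(
        refinement, thickness=cortical_outer - cage_inner, radii=radii
    )
    r = np.linalg.norm(mesh.element_coords().mean(axis=1), axis=1)
    cage_mask = r < cage_outer
    bone_E = np.where(r >= cancellous_outer, cortical_E, cancellous_E)
    bone_nu = np.full(mesh.n_elements, 0.3)
    return CageAssembly(
        mesh=mesh,
        case=case,
        cage_mask=cage_mask,
        bone_E=bone_E,
        bone_nu=bone_nu,
        interface_radius=cage_outer,
    )


def assembly_interface_elements(assembly: CageAssembly) -> np.ndarray:
    """Indices of cage elements touching the bone-implant interface."""
    coords = assembly.mesh.element_coords()
    r_outer = np.linalg.norm(coords, axis=2).max(axis=1)
    touch = np.abs(r_outer - assembly.interface_radius) < 1e-6
    return np.flatnonzero(touch & assembly.cage_mask)


def cage_interface_path(mesh: MacroMesh, case: LoadCase) -> np.ndarray:
    """Ordered outer-surface node path from one flange end over the apex to the other.

    The "bone-implant interface" analog: the outer surface centreline,
    running from the distal flange end to the proximal one.
    """
    outer_r = np.linalg.norm(mesh.nodes, axis=1).max()
    on_outer = np.abs(np.linalg.norm(mesh.nodes, axis=1) - outer_r) < 1e-6
    # centreline: x closest to 0
    xs = np.abs(mesh.nodes[:, 0])
    tol = xs[on_outer].min() + 1e-6
    sel = np.flatnonzero(on_outer & (xs <= tol))
    order = np.argsort(mesh.nodes[sel, 2])  # sweep along the flange direction
    return sel[order]
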