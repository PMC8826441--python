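"""Linear elasticity on hexahedral macro meshes (mm-N-MPa unit system).

Element stiffnesses come either from a per-element density field through the
density-property surrogate (the lattice implant model) or from a
heterogeneous bone material field.  The assembled system ``K U = F`` is
solved directly; compliance ``c = U^T K U``, per-element strain energies
``dc_e = u_e^T k_e u_e`` (the optimizer's sensitivities/fitness) and
centroid von Mises stresses are derived from the solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from ._hex8 import centroid_b_matrices, element_stiffness_batch, isotropic_stiffness


class SingularityError(RuntimeError):
    """Raised when the constrained stiffness matrix is singular."""


@dataclass
class MacroMesh:
    """Hexahedral mesh with kinematic constraints and nodal loads.

    ``fixed_dofs`` is a list of ``(node, direction)`` pairs (direction 0/1/2);
    ``loads`` a list of ``(node, direction, magnitude_N)``.
    """

    nodes: np.ndarray  # (nn, 3), mm
    elements: np.ndarray  # (ne, 8) int, VTK hex ordering
    fixed_dofs: list = field(default_factory=list)
    loads: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def ndof(self) -> int:
        return 3 * self.n_nodes

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]

    def edof(self) -> np.ndarray:
        return (3 * self.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)

    def load_vector(self) -> np.ndarray:
        F = np.zeros(self.ndof)
        for node, direction, mag in self.loads:
            F[3 * int(node) + int(direction)] += mag
        return F

    def fixed_mask(self) -> np.ndarray:
        mask = np.zeros(self.ndof, dtype=bool)
        for node, direction in self.fixed_dofs:
            mask[3 * int(node) + int(direction)] = True
        return mask

    def boundary_faces(self) -> np.ndarray:
        """Quad faces (node index 4-tuples) appearing in exactly one element."""
        FACE_LOCAL = np.array(
            [
                [0, 3, 2, 1],
                [4, 5, 6, 7],
                [0, 1, 5, 4],
                [2, 3, 7, 6],
                [1, 2, 6, 5],
                [0, 4, 7, 3],
            ]
        )
        faces = self.elements[:, FACE_LOCAL].reshape(-1, 4)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]


@dataclass
class Assembly:
    """Assembled stiffness with its ingredients kept for post-processing."""

    K: csr_matrix
    Ke: np.ndarray  # (ne, 24, 24), material included
    edof: np.ndarray
    E: np.ndarray  # per-element modulus, MPa
    nu: np.ndarray


@dataclass
class SolutionState:
    """Displacements, compliance and the per-element energy bookkeeping."""

    U: np.ndarray  # mm
    c: float  # compliance, N*mm
    element_energy: np.ndarray  # N*mm, sums to c
    residual: float
    vm: np.ndarray | None = None  # centroid von Mises, MPa
    assembly: Assembly | None = None


def assemble_from_moduli(mesh: MacroMesh, E: np.ndarray, nu: np.ndarray) -> Assembly:
    """Assemble ``K`` from explicit per-element isotropic constants."""
    E = np.broadcast_to(np.asarray(E, dtype=float), (mesh.n_elements,)).copy()
    nu = np.broadcast_to(np.asarray(nu, dtype=float), (mesh.n_elements,)).copy()
    C = np.array([isotropic_stiffness(e, n) for e, n in zip(E, nu)])
    Ke = element_stiffness_batch(mesh.element_coords(), C)
    edof = mesh.edof()
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(mesh.ndof, mesh.ndof)).tocsr()
    return Assembly(K=K, Ke=Ke, edof=edof, E=E, nu=nu)


def assemble(mesh: MacroMesh, densities, surrogate) -> Assembly:
    """Assemble with the lattice material law ``(E_bar(rho), nu_bar(rho))``.

    ``densities`` is a per-element relative density array or a DensityField.
    """
    rho = np.asarray(getattr(densities, "rho", densities), dtype=float)
    return assemble_from_moduli(mesh, surrogate.modulus(rho), surrogate.poisson(rho))


def assemble_material(mesh: MacroMesh, material) -> Assembly:
    """Assemble from a heterogeneous bone MaterialField."""
    return assemble_from_moduli(mesh, material.E, material.nu)


def solve(mesh: MacroMesh, assembly: Assembly) -> SolutionState:
    """Solve ``K U = F`` under the mesh constraints.

    Raises :class:`SingularityError` when the constraints leave rigid-body
    modes (or the mesh is otherwise underconstrained).
    """
    F = mesh.load_vector()
    fixed = mesh.fixed_mask()
    free = ~fixed
    if not fixed.any():
        raise SingularityError("no fixed dofs: rigid-body modes present")
    Kff = assembly.K[free][:, free].tocsc()
    U = np.zeros(mesh.ndof)
    try:
        lu = splu(Kff)
        U[free] = lu.solve(F[free])
    except RuntimeError as err:
        raise SingularityError(f"stiffness factorization failed: {err}") from err
    if not np.all(np.isfinite(U)):
        raise SingularityError("singular constrained stiffness (non-finite solution)")
    fnorm = np.linalg.norm(F[free])
    residual = (
        0.0
        if fnorm == 0.0
        else float(np.linalg.norm(Kff @ U[free] - F[free])) / fnorm
    )
    if residual > 1e-8:
        raise SingularityError(f"solver residual {residual:.2e} exceeds 1e-8")
    Ue = U[assembly.edof]  # (ne, 24)
    element_energy = np.einsum("ei,eij,ej->e", Ue, assembly.Ke, Ue)
    c = float(F @ U)
    return SolutionState(
        U=U,
        c=c,
        element_energy=element_energy,
        residual=residual,
        assembly=assembly,
    )


def von_mises(
    state: SolutionState,
    mesh: MacroMesh,
    densities=None,
    surrogate=None,
) -> np.ndarray:
    """Centroid von Mises stress per element, MPa.

    Material constants are taken from the assembly used for the solve; the
    ``densities``/``surrogate`` pair may be passed to evaluate a different
    material on the same displacement field.
    """
    if densities is not None and surrogate is not None:
        rho = np.asarray(getattr(densities, "rho", densities), dtype=float)
        E, nu = surrogate.modulus(rho), surrogate.poisson(rho)
    else:
        if state.assembly is None:
            raise ValueError("state carries no assembly; pass densities and surrogate")
        E, nu = state.assembly.E, state.assembly.nu
    B = centroid_b_matrices(mesh.element_coords())  # (ne, 6, 24)
    Ue = state.U[mesh.edof()]
    strain = np.einsum("eij,ej->ei", B, Ue)  # engineering shear components
    C = np.array([isotropic_stiffness(e, n) for e, n in zip(np.atleast_1d(E), np.atleast_1d(nu))])
    stress = np.einsum("eij,ej->ei", C, strain)
    s11, s22, s33, s12, s13, s23 = stress.T
    vm = np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s13**2 + s23**2)
    )
    state.vm = vm
    return vm


class InvalidPathError(ValueError):
    pass


def interface_profile(
    state: SolutionState, mesh: MacroMesh, node_path
) -> np.ndarray:
    """Von Mises stress sampled along an ordered surface node path.

    Returns an ``(npts, 2)`` array of (arc position mm, von Mises MPa); the
    stress at a node is the mean over its adjacent elements' centroid values.
    """
    node_path = np.asarray(node_path, dtype=int)
    if node_path.ndim != 1 or node_path.size == 0:
        raise InvalidPathError("node path must be a non-empty 1D index list")
    if node_path.min() < 0 or node_path.max() >= mesh.n_nodes:
        raise InvalidPathError("path node not in mesh")
    surface = set(np.unique(mesh.boundary_faces()).tolist())
    off_surface = [int(n) for n in node_path if int(n) not in surface]
    if off_surface:
        raise InvalidPathError(f"path nodes not on the mesh surface: {off_surface[:10]}")
    vm = state.vm if state.vm is not None else von_mises(state, mesh)
    # node -> adjacent elements
    prof = np.empty((len(node_path), 2))
    arc = 0.0
    prev = None
    for i, n in enumerate(node_path):
        if prev is not None:
            arc += float(np.linalg.norm(mesh.nodes[n] - mesh.nodes[prev]))
        adj = np.any(mesh.elements == n, axis=1)
        prof[i] = (arc, float(vm[adj].mean()))
        prev = n
    return prof


def write_profile_csv(profile: np.ndarray, path: str | Path) -> None:
    np.savetxt(
        path,
        profile,
        delimiter=",",
        header="arc_mm,von_mises_MPa",
        comments="",
    )
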