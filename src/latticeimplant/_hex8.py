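"""Trilinear 8-node hexahedral element kernels shared by the micro- and macro-scale solvers.

Voigt convention throughout: strains ordered (11, 22, 33, 12, 13, 23) with
engineering shear strains, so an isotropic stiffness has ``mu`` on the three
trailing diagonal entries.  Node ordering follows the VTK_HEXAHEDRON
convention: bottom face counter-clockwise, then top face.
"""

from __future__ import annotations

import numpy as np

#: Reference-cube corner signs in VTK hexahedron order.
XI_NODES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

#: 2x2x2 Gauss points (weight 1 each) on the reference cube.
GAUSS_PTS = XI_NODES / np.sqrt(3.0)


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt order (11,22,33,12,13,23)."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Reference-coordinate gradients dN/dxi, shape (8, 3), at point ``xi``."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = XI_NODES[a]
        g[a, 0] = 0.125 * sx * (1 + sy * xi[1]) * (1 + sz * xi[2])
        g[a, 1] = 0.125 * sy * (1 + sx * xi[0]) * (1 + sz * xi[2])
        g[a, 2] = 0.125 * sz * (1 + sx * xi[0]) * (1 + sy * xi[1])
    return g


def _b_matrix(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) from physical gradients dN (8 x 3)."""
    B = np.zeros((6, 24))
    for a in range(8):
        dx, dy, dz = dN[a]
        c = 3 * a
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c] = dz
        B[4, c + 2] = dx
        B[5, c + 1] = dz
        B[5, c + 2] = dy
    return B


def cube_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """Exact 24x24 stiffness of an axis-aligned cube element of edge ``h``.

    Uses 2x2x2 Gauss quadrature, which integrates the trilinear hexahedron
    stiffness exactly for an undistorted element.
    """
    C = isotropic_stiffness(E, nu)
    J = h / 2.0  # diagonal Jacobian entry
    detJ = J**3
    Ke = np.zeros((24, 24))
    for xi in GAUSS_PTS:
        dN = shape_gradients(xi) / J
        B = _b_matrix(dN)
        Ke += B.T @ C @ B * detJ
    return Ke


def element_stiffness_batch(coords: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Stiffness matrices for a batch of general hexahedra.

    Parameters
    ----------
    coords
        Node coordinates, shape (nelem, 8, 3), VTK ordering.
    C
        Either a single 6x6 elasticity matrix shared by all elements or an
        array of shape (nelem, 6, 6).

    Returns
    -------
    (nelem, 24, 24) array of element stiffness matrices.
    """
    coords = np.asarray(coords, dtype=float)
    nelem = coords.shape[0]
    shared = C.ndim == 2
    Ke = np.zeros((nelem, 24, 24))
    for xi in GAUSS_PTS:
        g = shape_gradients(xi)  # (8, 3)
        Jac = np.einsum("ai,eaj->eij", g, coords)  # (nelem, 3, 3)
        detJ = np.linalg.det(Jac)
        if np.any(detJ <= 0):
            bad = np.flatnonzero(detJ <= 0)
            raise ValueError(f"non-positive Jacobian in elements {bad[:10].tolist()}")
        Jinv = np.linalg.inv(Jac)
        dN = np.einsum("eij,aj->eai", Jinv, g)  # physical gradients, (nelem, 8, 3)
        B = np.zeros((nelem, 6, 24))
        cols = 3 * np.arange(8)
        B[:, 0, cols] = dN[:, :, 0]
        B[:, 1, cols + 1] = dN[:, :, 1]
        B[:, 2, cols + 2] = dN[:, :, 2]
        B[:, 3, cols] = dN[:, :, 1]
        B[:, 3, cols + 1] = dN[:, :, 0]
        B[:, 4, cols] = dN[:, :, 2]
        B[:, 4, cols + 2] = dN[:, :, 0]
        B[:, 5, cols + 1] = dN[:, :, 2]
        B[:, 5, cols + 2] = dN[:, :, 1]
        if shared:
            CB = np.einsum("ij,ejk->eik", C, B)
        else:
            CB = np.einsum("eij,ejk->eik", C, B)
        Ke += np.einsum("eji,ejk,e->eik", B, CB, detJ)
    return Ke


def centroid_b_matrices(coords: np.ndarray) -> np.ndarray:
    """Centroid strain-displacement matrices, shape (nelem, 6, 24)."""
    coords = np.asarray(coords, dtype=float)
    nelem = coords.shape[0]
    g = shape_gradients(np.zeros(3))
    Jac = np.einsum("ai,eaj->eij", g, coords)
    Jinv = np.linalg.inv(Jac)
    dN = np.einsum("eij,aj->eai", Jinv, g)
    B = np.zeros((nelem, 6, 24))
    cols = 3 * np.arange(8)
    B[:, 0, cols] = dN[:, :, 0]
    B[:, 1, cols + 1] = dN[:, :, 1]
    B[:, 2, cols + 2] = dN[:, :, 2]
    B[:, 3, cols] = dN[:, :, 1]
    B[:, 3, cols + 1] = dN[:, :, 0]
    B[:, 4, cols] = dN[:, :, 2]
    B[:, 4, cols + 2] = dN[:, :, 0]
    B[:, 5, cols + 1] = dN[:, :, 2]
    B[:, 5, cols + 2] = dN[:, :, 1]
    return B


def element_volumes(coords: np.ndarray) -> np.ndarray:
    """Volumes of a batch of hexahedra by Gauss quadrature."""
    coords = np.asarray(coords, dtype=float)
    vol = np.zeros(coords.shape[0])
    for xi in GAUSS_PTS:
        g = shape_gradients(xi)
        Jac = np.einsum("ai,eaj->eij", g, coords)
        vol += np.linalg.det(Jac)
    return vol
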