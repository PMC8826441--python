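"""Parametric stretching-dominated truss unit cells and the admissible design window.

The octet-truss cell (an octahedral core bridged to the cube corners by
tetrahedral struts) is the workhorse: its relative density follows the
classical closed form ``rho = 6*sqrt(2)*pi*(t/a)**2`` with ``t`` the strut
radius and ``a`` the strut length.  For a cubic cell of edge ``l`` every
octet strut has length ``a = l/sqrt(2)``.  Body-centred (bcc) and
face-centred (fcc) cells are provided for comparison.

The design window couples the manufacturing floor on printable strut
thickness with the clinical ceiling on pore size required for bone ingrowth,
and yields the admissible relative-density interval for a given cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

OCTET_DENSITY_COEFF = 6.0 * math.sqrt(2.0) * math.pi

#: Effective strut length per unit cell edge, accounting for face/interior
#: sharing between neighbouring cells in a periodic tiling.
_EFFECTIVE_STRUT_LENGTH = {
    "octet": 12.0 * math.sqrt(2.0),  # 12 interior octahedron edges + 24 half-owned face struts
    "bcc": 4.0 * math.sqrt(3.0),  # 8 interior half-diagonals
    "fcc": 6.0 * math.sqrt(2.0),  # 24 half-owned face struts
}

_STRUT_LENGTH_FACTOR = {
    "octet": 1.0 / math.sqrt(2.0),
    "bcc": math.sqrt(3.0) / 2.0,
    "fcc": 1.0 / math.sqrt(2.0),
}


def density_from_strut(t: float, l: float) -> float:
    """Relative density of an octet-truss lattice from strut radius and strut length.

    Implements ``rho = 6*sqrt(2)*pi*(t/l)**2`` clipped to 1, where ``l`` is the
    STRUT length (for a cubic octet cell of edge L, ``l = L/sqrt(2)``) and
    ``t`` the strut radius.  Porosity is ``1 - rho``.
    """
    if l <= 0:
        raise ValueError(f"strut length must be positive, got {l}")
    if t < 0:
        raise ValueError(f"strut radius must be non-negative, got {t}")
    return min(OCTET_DENSITY_COEFF * (t / l) ** 2, 1.0)


def strut_for_density(rho: float, l: float) -> float:
    """Strut radius producing relative density ``rho`` at strut length ``l``.

    Exact inverse of :func:`density_from_strut` on the unclipped branch.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if l <= 0:
        raise ValueError(f"strut length must be positive, got {l}")
    return l * math.sqrt(rho / OCTET_DENSITY_COEFF)


def _cell_density_coeff(cell_type: str) -> float:
    # rho = coeff * (t/L)^2 with L the cell edge, from strut-volume bookkeeping
    return _EFFECTIVE_STRUT_LENGTH[cell_type] * math.pi


@dataclass
class UnitCellSpec:
    """A parametric truss unit cell.

    Exactly two of ``t`` (strut radius, mm), ``l`` (cell edge, mm) and ``rho``
    (relative density) determine the third; ``l`` is always required.  The
    pore size is the face-diagonal opening ``l/sqrt(2) - 2 t`` (octet/fcc).
    """

    cell_type: str = "octet"
    l: float = 1.35
    t: float | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in _EFFECTIVE_STRUT_LENGTH:
            raise ValueError(f"unsupported cell type {self.cell_type!r}")
        if self.l <= 0:
            raise ValueError("cell edge length must be positive")
        coeff = _cell_density_coeff(self.cell_type)
        if self.t is None and self.rho is None:
            raise ValueError("provide strut radius t or relative density rho")
        if self.t is not None and self.rho is not None:
            implied = min(coeff * (self.t / self.l) ** 2, 1.0)
            if abs(implied - self.rho) > 1e-9 * max(self.rho, 1e-12):
                raise ValueError(
                    f"inconsistent spec: t={self.t}, l={self.l} imply rho={implied}, got {self.rho}"
                )
        elif self.t is not None:
            if self.t < 0:
                raise ValueError("strut radius must be non-negative")
            self.rho = min(coeff * (self.t / self.l) ** 2, 1.0)
        else:
            if not 0.0 <= self.rho <= 1.0:
                raise ValueError(f"rho must be in [0, 1], got {self.rho}")
            self.t = self.l * math.sqrt(self.rho / coeff)

    @property
    def strut_length(self) -> float:
        """Length of an individual strut, mm."""
        return self.l * _STRUT_LENGTH_FACTOR[self.cell_type]

    @property
    def porosity(self) -> float:
        return 1.0 - self.rho

    @property
    def pore(self) -> float:
        """Face-diagonal pore opening, mm (floored at zero)."""
        return max(self.l / math.sqrt(2.0) - 2.0 * self.t, 0.0)


@dataclass
class CellGeometry:
    """Wireframe of a unit cell: node coordinates (mm) and strut index pairs."""

    nodes: np.ndarray  # (n, 3)
    struts: np.ndarray  # (m, 2) int
    t: float  # strut radius, mm

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.struts = np.asarray(self.struts, dtype=int)
        n = len(self.nodes)
        if self.struts.size:
            if self.struts.min() < 0 or self.struts.max() >= n:
                raise ValueError("strut references a non-existent node")
            if np.any(self.struts[:, 0] == self.struts[:, 1]):
                raise ValueError("degenerate strut connecting a node to itself")
            key = {tuple(sorted(s)) for s in self.struts.tolist()}
            if len(key) != len(self.struts):
                raise ValueError("duplicate struts")

    @property
    def edge_length(self) -> float:
        """Cell edge inferred from the node bounding box, mm."""
        span = self.nodes.max(axis=0) - self.nodes.min(axis=0)
        return float(span.max())


@dataclass
class DesignWindow:
    """Clinical and manufacturing bounds on the cell morphology.

    ``t_min`` is a printable strut THICKNESS (diameter) when
    ``strut_size_is_diameter`` is true (the default), otherwise a radius.
    ``pore_max`` caps the pore opening so bone can grow through.
    """

    t_min: float = 0.2  # mm
    pore_max: float = 0.8  # mm
    l_range: tuple[float, float] = (1.2, 1.5)
    rho_bounds: tuple[float, float] = (0.2, 0.7)
    strut_size_is_diameter: bool = True

    def __post_init__(self) -> None:
        if self.t_min <= 0 or self.pore_max <= 0:
            raise ValueError("t_min and pore_max must be positive")
        lo, hi = self.rho_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("rho_bounds must be an interval inside (0, 1)")

    @property
    def min_radius(self) -> float:
        return self.t_min / 2.0 if self.strut_size_is_diameter else self.t_min


def _octet_wireframe(l: float) -> tuple[np.ndarray, np.ndarray]:
    corners = np.array(
        [[x, y, z] for x in (0.0, l) for y in (0.0, l) for z in (0.0, l)]
    )
    h = l / 2.0
    face_centers = np.array(
        [
            [0.0, h, h],
            [l, h, h],
            [h, 0.0, h],
            [h, l, h],
            [h, h, 0.0],
            [h, h, l],
        ]
    )
    nodes = np.vstack([corners, face_centers])
    struts: list[tuple[int, int]] = []
    # octahedral core: every pair of face centres except opposite faces
    for i in range(6):
        for j in range(i + 1, 6):
            if j == i + 1 and i % 2 == 0:
                continue  # opposite faces share no edge
            struts.append((8 + i, 8 + j))
    # tetrahedral corner struts: each corner to its three adjacent face centres
    for ci in range(8):
        c = corners[ci]
        for fi in range(6):
            axis = fi // 2
            if abs(face_centers[fi][axis] - c[axis]) < 1e-12:
                struts.append((ci, 8 + fi))
    return nodes, np.array(struts)


def _bcc_wireframe(l: float) -> tuple[np.ndarray, np.ndarray]:
    corners = np.array(
        [[x, y, z] for x in (0.0, l) for y in (0.0, l) for z in (0.0, l)]
    )
    nodes = np.vstack([corners, [[l / 2, l / 2, l / 2]]])
    struts = np.array([(i, 8) for i in range(8)])
    return nodes, struts


def _fcc_wireframe(l: float) -> tuple[np.ndarray, np.ndarray]:
    nodes, octet_struts = _octet_wireframe(l)
    struts = np.array([s for s in octet_struts.tolist() if s[0] < 8])
    return nodes, struts


def build_cell(spec: UnitCellSpec) -> CellGeometry:
    """Wireframe geometry of a unit cell on the cube ``[0, l]^3``.

    The octet cell carries an octahedral core of 6 face-centre nodes joined by
    12 struts, plus 24 corner struts forming the corner tetrahedra; bcc and
    fcc cells use their standard connectivity.
    """
    builders = {"octet": _octet_wireframe, "bcc": _bcc_wireframe, "fcc": _fcc_wireframe}
    try:
        builder = builders[spec.cell_type]
    except KeyError:
        raise ValueError(f"unsupported cell type {spec.cell_type!r}") from None
    nodes, struts = builder(spec.l)
    return CellGeometry(nodes=nodes, struts=struts, t=spec.t)


def octahedral_core(cell: CellGeometry, l: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Interior (octahedral-core) nodes and struts of an octet wireframe.

    A node belongs to the core when it does not lie on any face of the cell
    bounding box corner set; for the octet these are the six face centres
    joined by twelve struts.
    """
    if l is None:
        l = cell.edge_length
    on_corner = np.all(
        (np.abs(cell.nodes) < 1e-9) | (np.abs(cell.nodes - l) < 1e-9), axis=1
    )
    core_nodes = np.flatnonzero(~on_corner)
    core_set = set(core_nodes.tolist())
    core_struts = np.array(
        [s for s in cell.struts.tolist() if s[0] in core_set and s[1] in core_set],
        dtype=int,
    ).reshape(-1, 2)
    return core_nodes, core_struts


def pore_size(rho: float, l: float) -> float:
    """Pore opening (mm) of an octet cell of edge ``l`` at density ``rho``."""
    a = l / math.sqrt(2.0)
    t = strut_for_density(rho, a) if rho > 0 else 0.0
    return max(a - 2.0 * t, 0.0)


def admissible_window(win: DesignWindow, l: float) -> tuple[float, float]:
    """Admissible relative-density interval for cell edge ``l``, mm.

    Returns ``(rho_lo, rho_hi)``; the interval is empty when
    ``rho_lo > rho_hi``.  Low densities are excluded both by the printable
    strut-thickness floor and by the pore-size ceiling (thin struts mean wide
    pores); the upper end is capped by the window's density bounds.
    """
    a = l / math.sqrt(2.0)
    lo, hi = win.rho_bounds
    # manufacturing floor: radius >= min printable radius
    rho_t = density_from_strut(win.min_radius, a)
    # biological ceiling on pore opening: a - 2 t <= pore_max
    t_pore = max((a - win.pore_max) / 2.0, 0.0)
    rho_pore = density_from_strut(t_pore, a)
    rho_lo = max(lo, rho_t, rho_pore)
    return (rho_lo, hi)


def window_is_empty(interval: tuple[float, float]) -> bool:
    return interval[0] > interval[1]


def export_wireframe_csv(cell: CellGeometry, nodes_path: str | Path, struts_path: str | Path) -> None:
    """Write the wireframe as two CSVs: node coordinates and strut index pairs."""
    nodes_path, struts_path = Path(nodes_path), Path(struts_path)
    header_n = "x_mm,y_mm,z_mm"
    np.savetxt(nodes_path, cell.nodes, delimiter=",", header=header_n, comments="")
    with open(struts_path, "w") as fh:
        fh.write("node_a,node_b,radius_mm\n")
        for a, b in cell.struts:
            fh.write(f"{a},{b},{cell.t}\n")


def rotations_90() -> Iterable[np.ndarray]:
    """The 24 rotation matrices of the cubic point group."""
    mats = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        P = np.eye(3)[list(perm)]
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    R = np.diag([sx, sy, sz]) @ P
                    if np.isclose(np.linalg.det(R), 1.0):
                        mats.append(R)
    return mats
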