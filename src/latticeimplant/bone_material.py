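"""CT Hounsfield-value to bone-material mapping.

Bone tissue density scales linearly with the CT gray value (HU), and the
Young's modulus follows a piecewise law: cortical bone (HU >= 1500) is
assigned 17 GPa, marrow (HU <= 100) 20 MPa, and cancellous bone in between
follows the power law ``E = 2713 * rho0^2.36`` MPa with the apparent density
``rho0 = (HU/1500) * 2.0`` g/cm^3.  The outer branches win at the overlapping
breakpoints, and the mapping is applied as printed even though it is
discontinuous at HU = 1500 (2713 * 2^2.36 ~ 13.9 GPa vs 17 GPa).

A Poisson ratio of 0.3 is used for all bone tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CORTICAL_HU = 1500.0
MARROW_HU = 100.0
CORTICAL_E = 17000.0  # MPa
MARROW_E = 20.0  # MPa
CANCELLOUS_COEFF = 2713.0  # MPa per (g/cm^3)^2.36
CANCELLOUS_EXP = 2.36
BONE_NU = 0.3

TISSUE_LABELS = ("marrow", "cancellous", "cortical")


@dataclass
class VoxelVolume:
    """Scalar HU volume on a regular grid."""

    values: np.ndarray  # (nx, ny, nz), HU
    spacing: np.ndarray  # (3,), mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D grid")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive componentwise")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower corner, upper corner) of the volume, mm."""
        return self.origin, self.origin + self.spacing * np.array(self.values.shape)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[d] + (np.arange(self.values.shape[d]) + 0.5) * self.spacing[d]
            for d in range(3)
        ]
        return tuple(axes)

    def save(self, stem: str | Path) -> None:
        """Write as raw float32 plus a JSON header (``<stem>.raw``, ``<stem>.json``)."""
        import json

        stem = Path(stem)
        self.values.astype(np.float32).tofile(stem.with_suffix(".raw"))
        header = {
            "dims": list(self.values.shape),
            "spacing_mm": self.spacing.tolist(),
            "origin_mm": self.origin.tolist(),
            "dtype": "float32",
            "order": "C",
        }
        stem.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "VoxelVolume":
        import json

        stem = Path(stem)
        header = json.loads(stem.with_suffix(".json").read_text())
        values = np.fromfile(stem.with_suffix(".raw"), dtype=np.float32).reshape(
            header["dims"]
        )
        return cls(
            values=values.astype(float),
            spacing=np.array(header["spacing_mm"]),
            origin=np.array(header["origin_mm"]),
        )


@dataclass
class MaterialField:
    """Per-element bone material: Young's modulus, Poisson ratio, tissue label."""

    E: np.ndarray  # MPa
    nu: np.ndarray  # dimensionless, 0.3 everywhere
    tissue: np.ndarray  # str labels from TISSUE_LABELS

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        self.tissue = np.asarray(self.tissue)
        if np.any(self.E < MARROW_E) or np.any(self.E > CORTICAL_E):
            raise ValueError("bone modulus must lie in [20, 17000] MPa")


def hu_to_density(hu):
    """Apparent bone density, g/cm^3: ``(HU/1500) * 2.0`` floored at zero."""
    return np.maximum(np.asarray(hu, dtype=float) / CORTICAL_HU * 2.0, 0.0)


def hu_to_modulus(hu):
    """Piecewise Young's modulus, MPa, from the CT gray value."""
    hu = np.asarray(hu, dtype=float)
    rho0 = hu_to_density(hu)
    cancellous = CANCELLOUS_COEFF * rho0**CANCELLOUS_EXP
    out = np.where(hu >= CORTICAL_HU, CORTICAL_E, np.where(hu <= MARROW_HU, MARROW_E, cancellous))
    return out if out.ndim else float(out)


def tissue_label(hu):
    """Tissue classification following the modulus branches."""
    hu = np.asarray(hu, dtype=float)
    out = np.where(
        hu >= CORTICAL_HU, "cortical", np.where(hu <= MARROW_HU, "marrow", "cancellous")
    )
    return out if out.ndim else str(out)


class OutOfExtentError(ValueError):
    def __init__(self, element_ids):
        self.element_ids = list(element_ids)
        super().__init__(
            f"{len(self.element_ids)} element(s) outside the volume extent: "
            f"{self.element_ids[:10]}"
        )


def map_volume(vol: VoxelVolume, mesh, *, n_bins: int | None = None) -> MaterialField:
    """Assign heterogeneous bone materials to macro-mesh elements.

    Each element receives the mean HU of the voxels whose centres fall inside
    its bounding box (nearest voxel to the centroid as fallback for elements
    smaller than a voxel); the modulus and tissue label follow the piecewise
    law.  ``n_bins`` optionally quantizes the element HU values into that many
    discrete materials before conversion.
    """
    lo, hi = vol.extent
    coords = mesh.nodes[mesh.elements]  # (ne, 8, 3)
    el_lo = coords.min(axis=1)
    el_hi = coords.max(axis=1)
    outside = np.any(el_lo < lo - 1e-9, axis=1) | np.any(el_hi > hi + 1e-9, axis=1)
    if np.any(outside):
        raise OutOfExtentError(np.flatnonzero(outside))

    ax, ay, az = vol.voxel_centers()
    hu_elem = np.empty(len(coords))
    for e in range(len(coords)):
        sel = (
            np.searchsorted(ax, el_lo[e, 0]),
            np.searchsorted(ax, el_hi[e, 0]),
            np.searchsorted(ay, el_lo[e, 1]),
            np.searchsorted(ay, el_hi[e, 1]),
            np.searchsorted(az, el_lo[e, 2]),
            np.searchsorted(az, el_hi[e, 2]),
        )
        block = vol.values[sel[0] : sel[1], sel[2] : sel[3], sel[4] : sel[5]]
        if block.size:
            hu_elem[e] = block.mean()
        else:  # element smaller than a voxel: nearest voxel to the centroid
            c = coords[e].mean(axis=0)
            i = np.clip(((c - vol.origin) / vol.spacing).astype(int), 0, np.array(vol.values.shape) - 1)
            hu_elem[e] = vol.values[tuple(i)]
    if n_bins is not None:
        edges = np.linspace(hu_elem.min(), hu_elem.max(), n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hu_elem = centers[np.clip(np.digitize(hu_elem, edges) - 1, 0, n_bins - 1)]
    return MaterialField(
        E=hu_to_modulus(hu_elem),
        nu=np.full(len(hu_elem), BONE_NU),
        tissue=tissue_label(hu_elem),
    )


def field_to_csv(field: MaterialField, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"E_MPa": field.E, "nu": field.nu, "tissue": field.tissue}
    ).to_csv(path, index_label="element")
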