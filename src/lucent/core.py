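"""Core data carriers shared across the pipeline.

A :class:`CTVolume` is a scalar 3D image with voxel spacing in millimetres.
Airway masks are plain boolean :class:`numpy.ndarray` objects aligned
voxel-for-voxel with the volume they annotate; spacing is carried alongside
wherever it matters (surface distances, meshing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: intensity domains a volume can be in
HU = "HU"
UNIT = "unit_normalized"


@dataclass
class CTVolume:
    """Scalar 3D image with spacing, axes ordered (x, y, z), z cranio-caudal.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities, Hounsfield units or [0, 1] normalized.
    spacing_mm : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin_mm : tuple of float
        World position of voxel (0, 0, 0).
    intensity_domain : {"HU", "unit_normalized"}
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_domain: str = HU

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.voxels.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.intensity_domain not in (HU, UNIT):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, **kw) -> "CTVolume":
        """Copy of this volume with new voxel data (and optional field overrides)."""
        return replace(self, voxels=voxels, **kw)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI with spacing in the affine diagonal."""
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        img = nib.Nifti1Image(self.voxels.astype(np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, intensity_domain: str = HU) -> "CTVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(
            np.asanyarray(img.dataobj).astype(np.float32),
            spacing_mm=spacing,
            origin_mm=origin,
            intensity_domain=intensity_domain,
        )


def save_mask(mask: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write a binary mask as uint8 NIfTI with spacing in the header."""
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary mask NIfTI; returns (bool array, spacing_mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj) > 0.5, spacing
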