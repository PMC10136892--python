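"""In-memory containers for image volumes and region masks.

A :class:`VoxelGrid` is a 3-D scalar field (SUV for PET, HU for CT) with
anisotropic voxel spacing in millimetres; a :class:`RoiMask` is a boolean
field on the same lattice, tagged with the reader that produced it and its
role (liver reference or tumor). Both round-trip through NIfTI via nibabel,
with the spacing carried in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryMismatchError

_SPACING_ATOL = 1e-6


@dataclass
class VoxelGrid:
    """3-D scalar volume with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelGrid":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing)


@dataclass
class RoiMask:
    """Binary mask aligned to a VoxelGrid, tagged with reader and role."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    reader: str | None = None
    role: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("RoiMask requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, reader: str | None = None,
                   role: str | None = None) -> "RoiMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0.5, spacing, reader=reader, role=role)


def same_geometry(a: VoxelGrid | RoiMask, b: VoxelGrid | RoiMask) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing, b.spacing, atol=_SPACING_ATOL)


def require_aligned(a: VoxelGrid | RoiMask, b: VoxelGrid | RoiMask, what: str = "inputs") -> None:
    if not same_geometry(a, b):
        raise GeometryMismatchError(
            f"{what} are not on the same grid: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap of two masks on the same grid."""
    require_aligned(a, b, "masks")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)
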