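"""PERCIST-style liver-referenced SUV thresholding and tumor delineation.

The FDG-positive tumor volume is defined by the liver-referenced threshold
T = 1.5 * mean liver SUV + 2 * SD(liver SUV); voxels with SUV >= T form the
tumor label map after removal of physiological-uptake regions (supplied as
exclusion masks, standing in for the readers' manual edits) and of connected
components below a minimum size. The label map can then be transferred to
the CT grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryMismatchError, InvalidReferenceError, NoTumorFoundError
from .grids import RoiMask, VoxelGrid, require_aligned, same_geometry

# 26-neighbourhood connectivity in 3-D for component labelling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LiverStats:
    """Mean and sample SD of SUV over the liver reference region."""

    mean_suv: float
    sd_suv: float
    n_voxels: int


@dataclass
class SegmentationResult:
    threshold_suv: float
    tumor_mask: RoiMask
    n_components: int
    total_mtv_ml: float


def liver_reference_stats(pet: VoxelGrid, liver_mask: RoiMask) -> LiverStats:
    """Liver SUV statistics; SD uses the sample (n-1) convention."""
    require_aligned(pet, liver_mask, "PET and liver mask")
    values = pet.data[liver_mask.data]
    if values.size == 0:
        raise InvalidReferenceError("liver reference mask is empty")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return LiverStats(mean_suv=float(values.mean()), sd_suv=sd,
                      n_voxels=int(values.size))


def percist_threshold(stats: LiverStats) -> float:
    """Liver-referenced SUV threshold: 1.5 * mean + 2 * SD (affine, no floor)."""
    return 1.5 * stats.mean_suv + 2.0 * stats.sd_suv


def segment_lesions(pet: VoxelGrid, threshold: float,
                    exclusion_masks: list[RoiMask] | None = None,
                    min_voxels: int = 2) -> SegmentationResult:
    """Threshold the PET volume and keep sufficiently large components.

    Inclusion rule is SUV >= threshold (ties kept). Exclusion masks emulate
    manual removal of physiological uptake (liver, heart, bladder).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = pet.data >= threshold
    for excl in exclusion_masks or []:
        require_aligned(pet, excl, "PET and exclusion mask")
        mask &= ~excl.data

    labels, n_comp = ndimage.label(mask, structure=_STRUCT_26)
    if n_comp and min_voxels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        keep = np.ones(n_comp + 1, dtype=bool)
        keep[small] = False
        keep[0] = False
        mask = keep[labels]
        n_comp = int(np.count_nonzero(counts[1:] >= min_voxels))
    if not mask.any():
        raise NoTumorFoundError(
            f"no FDG-positive tumor at threshold {threshold:.3f} SUV"
        )
    roi = RoiMask(mask, pet.spacing, role="tumor")
    return SegmentationResult(
        threshold_suv=float(threshold),
        tumor_mask=roi,
        n_components=int(n_comp),
        total_mtv_ml=roi.volume_ml(),
    )


def transfer_labelmap(tumor_mask: RoiMask, target: VoxelGrid) -> RoiMask:
    """Transfer the tumor label map onto the target (CT) grid.

    Identical grids pass through unchanged; otherwise the grids must cover the
    same physical extent and the mask is nearest-neighbour resampled.
    """
    if same_geometry(tumor_mask, target):
        return RoiMask(tumor_mask.data.copy(), target.spacing,
                       reader=tumor_mask.reader, role=tumor_mask.role)
    src_extent = np.asarray(tumor_mask.shape) * np.asarray(tumor_mask.spacing)
    dst_extent = np.asarray(target.shape) * np.asarray(target.spacing)
    if not np.allclose(src_extent, dst_extent, rtol=1e-3):
        raise GeometryMismatchError(
            "label map and target grid cover different physical extents; "
            "supply a resampling transform"
        )
    zoom = np.asarray(target.shape) / np.asarray(tumor_mask.shape)
    resampled = ndimage.zoom(tumor_mask.data.astype(np.uint8), zoom, order=0)
    # order=0 zoom can be off by one voxel in shape on non-integer factors
    resampled = resampled[tuple(slice(0, s) for s in target.shape)]
    if resampled.shape != tuple(target.shape):
        pad = [(0, t - s) for s, t in zip(resampled.shape, target.shape)]
        resampled = np.pad(resampled, pad)
    return RoiMask(resampled > 0, target.spacing,
                   reader=tumor_mask.reader, role=tumor_mask.role)
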