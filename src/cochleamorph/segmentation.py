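"""Label construction: thresholding, speckle removal, label arithmetic, masking.

This mirrors the interactive micro-CT workflow — select bone by intensity
threshold, clean up noise, combine/subtract labels, then multiply the label
back into the grayscale image to isolate the labelled anatomy — as
deterministic array operations.  The manual brush-based noise cleanup of the
interactive workflow is replaced by connected-component size filtering, which
is a surrogate, not a claim of equivalence.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io_formats import LabelMask, VoxelVolume, check_same_geometry

__all__ = [
    "ThresholdRule",
    "threshold_segment",
    "remove_small_components",
    "subtract_labels",
    "apply_mask",
]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass(frozen=True)
class ThresholdRule:
    """Closed intensity interval [lo, hi] selecting voxels; hi may be +inf."""

    lo: float
    hi: float = math.inf

    def __post_init__(self) -> None:
        if math.isnan(self.lo) or math.isnan(self.hi):
            raise ParameterError("threshold bounds must not be NaN")
        if self.lo > self.hi:
            raise ParameterError(f"threshold lo {self.lo} exceeds hi {self.hi}")


def threshold_segment(volume: VoxelVolume, rule: ThresholdRule) -> LabelMask:
    """Binary mask of voxels whose intensity lies in [rule.lo, rule.hi]."""
    data = volume.data
    mask = (data >= rule.lo) & (data <= rule.hi)
    return LabelMask(mask.astype(np.uint8), volume.voxel_size_um, volume.origin_mm)


def remove_small_components(
    mask: LabelMask, min_voxels: int = 27, connectivity: int = 26
) -> LabelMask:
    """Drop connected components smaller than ``min_voxels``.

    Deterministic stand-in for manual noise brushing.  Idempotent, never adds
    voxels.  ``connectivity`` is 6 (faces), 18 (+edges) or 26 (+corners).
    """
    if min_voxels < 1:
        raise ParameterError(f"min_voxels must be >= 1, got {min_voxels}")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ParameterError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    binary = mask.astype_bool()
    labels, n = ndimage.label(binary, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return LabelMask(np.zeros_like(mask.data, dtype=np.uint8), mask.voxel_size_um, mask.origin_mm)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    out = keep[labels]
    return LabelMask(out.astype(np.uint8), mask.voxel_size_um, mask.origin_mm)


def subtract_labels(a: LabelMask, b: LabelMask) -> LabelMask:
    """Voxelwise a AND NOT b (the subtracted-label recipe for apical soft tissue)."""
    check_same_geometry(a, b)
    out = a.astype_bool() & ~b.astype_bool()
    return LabelMask(out.astype(np.uint8), a.voxel_size_um, a.origin_mm)


def apply_mask(volume: VoxelVolume, mask: LabelMask) -> VoxelVolume:
    """Multiply the grayscale volume by the {0,1} mask, isolating labelled anatomy."""
    check_same_geometry(volume, mask)
    out = volume.data * mask.astype_bool()
    return VoxelVolume(out.astype(volume.data.dtype), volume.voxel_size_um, volume.origin_mm)
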