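"""Mask-to-measurement conversion: gap-inclusive volume and reference-slice area.

Volumes count segmented voxels times the full voxel footprint
``dx * dy * slice_spacing`` with ``slice_spacing = thickness + gap``: the CSF
in the unsampled gap between excited slabs is attributed to the adjacent
slices, as in routine clinical volumetry on gapped 2D acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .image import VoiMask

__all__ = [
    "VentricleMetrics",
    "mask_volume",
    "select_reference_slice",
    "mask_area",
    "average_metrics",
]


def mask_volume(mask: VoiMask, pixel_size: tuple[float, float], slice_spacing: float) -> float:
    """Lateral-ventricle volume (mL) of a 3D mask, gap included.

    ``N_voxels * dx * dy * slice_spacing / 1000`` (mm^3 to mL).
    """
    if mask.data.ndim != 3:
        raise ValidationError("mask_volume expects a 3D mask")
    dx, dy = pixel_size
    if dx <= 0 or dy <= 0 or slice_spacing <= 0:
        raise ValidationError(f"nonpositive geometry: pixel {(dx, dy)}, spacing {slice_spacing}")
    return mask.n_voxels * dx * dy * slice_spacing / 1000.0


def select_reference_slice(mask: VoiMask, mode: str = "auto", index: int | None = None) -> int:
    """Choose the axial reference slice on which the 2D area is measured.

    ``mode="explicit"`` passes through a user-chosen index (the clinical
    workflow: the plane through the anterior horns and bodies, set on a
    sagittal scout).  ``mode="auto"`` returns the slice containing the mask
    centroid (floor on ties), a reproducible surrogate used on phantoms.
    """
    if mask.data.ndim != 3:
        raise ValidationError("reference-slice selection expects a 3D mask")
    if mask.is_empty():
        raise ValidationError("empty mask")
    if mode == "explicit":
        if index is None:
            raise ValidationError("explicit mode requires an index")
        if not (0 <= index < mask.data.shape[2]):
            raise ValidationError(f"index {index} outside axial extent {mask.data.shape[2]}")
        return int(index)
    if mode != "auto":
        raise ValidationError(f"unknown mode {mode!r}")
    zc = np.nonzero(mask.data)[2]
    return int(math.floor(zc.mean()))


def mask_area(mask: VoiMask, pixel_size: tuple[float, float]) -> float:
    """Lateral-ventricle area (cm^2) of a 2D mask: ``N_pixels * dx * dy / 100``."""
    if mask.data.ndim != 2:
        raise ValidationError("mask_area expects a 2D mask")
    dx, dy = pixel_size
    if dx <= 0 or dy <= 0:
        raise ValidationError(f"nonpositive pixel size {(dx, dy)}")
    return mask.n_voxels * dx * dy / 100.0


@dataclass(frozen=True)
class VentricleMetrics:
    """A per-sequence set of measurements and their arithmetic mean."""

    per_sequence: tuple[float, ...]
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.per_sequence:
            raise ValidationError("at least one per-sequence value is required")
        if any(v < 0 for v in self.per_sequence):
            raise ValidationError("measurements must be nonnegative")
        object.__setattr__(self, "mean", float(np.mean(self.per_sequence)))


def average_metrics(values: list[float]) -> VentricleMetrics:
    """Average one metric over the sequences it was measured on.

    Clinically, volumes are measured on two 3D sequences and areas on two 2D
    sequences; each patient's LvV / LvA is the mean of the respective pair.
    """
    return VentricleMetrics(per_sequence=tuple(float(v) for v in values))
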