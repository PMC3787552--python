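"""Shared image containers.

The anatomical grid convention used throughout the package:

* arrays are indexed ``(x, y, z)`` with the axial (slice) axis last;
* voxel centers sit at ``(i + 0.5) * pixel`` in-plane and
  ``(k + 0.5) * slice_spacing`` through-plane;
* ``slice_spacing = thickness + gap`` (center-to-center), so a voxel's
  through-plane footprint for volumetry purposes spans the whole spacing,
  gap included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ImageVolume", "VoiMask"]


@dataclass
class ImageVolume:
    """A 3D scalar image with anisotropic spacing and slice-gap metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units.
    pixel_size : (float, float)
        In-plane voxel size ``(dx, dy)`` in mm.
    thickness : float
        Excited slab thickness in mm.
    gap : float
        Inter-slice gap in mm; ``0`` for contiguous slices.
    meta : dict
        Free-form provenance (seed, generator parameters, ...).
    """

    data: np.ndarray
    pixel_size: tuple[float, float]
    thickness: float
    gap: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.data.ndim}")
        dx, dy = self.pixel_size
        if dx <= 0 or dy <= 0:
            raise ValidationError(f"pixel size must be positive, got {(dx, dy)}")
        if self.thickness <= 0:
            raise ValidationError(f"slice thickness must be positive, got {self.thickness}")
        if self.gap < 0:
            raise ValidationError(f"slice gap must be nonnegative, got {self.gap}")

    @property
    def slice_spacing(self) -> float:
        """Center-to-center axial spacing in mm (thickness + gap)."""
        return self.thickness + self.gap

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def slice(self, k: int) -> np.ndarray:
        """Axial slice ``k`` as a 2D ``(nx, ny)`` view."""
        return self.data[:, :, k]


@dataclass
class VoiMask:
    """Binary volume/slice of interest, congruent with its source image.

    ``provenance`` records which stage produced the mask: ``"levelset"`` for
    the raw contour, ``"refined"`` after Otsu partial-volume stripping,
    ``"truth"`` for phantom ground truth.
    """

    data: np.ndarray
    provenance: str = "levelset"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValidationError(f"mask must be 2D or 3D, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())
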