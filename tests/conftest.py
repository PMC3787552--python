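"""Shared fixtures.

The expensive fixture is ``phantom_batch``: ten anatomical phantoms spanning
small-dementia to hydrocephalic ventricle volumes (~20-260 mL), each
segmented once; it is session-scoped so the volume-recovery and
area-to-volume agreement tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from lvmorph import (
    LevelSetParams,
    default_ventricle_spec,
    make_ventricle_phantom,
    segment_ventricles,
)

BATCH_SCALES = np.linspace(1.0, 2.35, 10)
SEG_PARAMS = LevelSetParams(iterations=400, smoothing=1)


@pytest.fixture(scope="session")
def phantom_batch():
    """(spec, volume, truth, segmentation) for ten phantoms of 20-260 mL."""
    batch = []
    for i, scale in enumerate(BATCH_SCALES):
        spec = default_ventricle_spec(float(scale), seed=i)
        vol, truth = make_ventricle_phantom(spec)
        seg = segment_ventricles(vol, truth.seed_points(), spec.polarity, SEG_PARAMS)
        batch.append((spec, vol, truth, seg))
    return batch


@pytest.fixture
def disk_image():
    """A sharp dark disk (radius 14 px) on a bright background, with its mask."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    disk = (xx - 32) ** 2 + (yy - 32) ** 2 <= 14**2
    img = np.where(disk, 20.0, 120.0)
    return img, disk


@pytest.fixture
def blurred_disk_image(disk_image):
    img, disk = disk_image
    return ndimage.gaussian_filter(img, 1.0), disk
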