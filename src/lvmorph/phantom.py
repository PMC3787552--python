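"""Synthetic data generators with analytic ground truth.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`make_ventricle_phantom` — anatomical volumes containing two mirrored
  ventricle-shaped CSF compartments (a "body" plus an "anterior horn"
  ellipsoid per side), rendered on a fine grid, blurred (partial-volume
  surrogate), resampled onto a coarse acquisition grid with a 5 mm slab and an
  inter-slice gap, and degraded with additive Gaussian noise.  Ground truth
  (volume, mask, reference-slice area) is computed on the fine grid *before*
  any degradation, so it is the acceptance oracle for segmentation and
  volumetry.
* :func:`make_flow_phantom` — velocity-encoded phase stacks for a small
  circular lumen carrying a periodic, zero-mean flow waveform, with the true
  stroke volume evaluated on the continuous waveform.
* :func:`make_cohort` — tables of paired (area, volume) values following a
  linear relation plus noise, for regression and agreement studies.

Every generator draws all randomness from a single integer seed carried by its
spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import AliasingError, ValidationError
from .flowquant import FlowSeries
from .image import ImageVolume, VoiMask

__all__ = [
    "Lobe",
    "PhantomSpec",
    "PhantomTruth",
    "FlowPhantomSpec",
    "CohortSpec",
    "GroupSpec",
    "default_ventricle_spec",
    "make_ventricle_phantom",
    "make_flow_phantom",
    "flow_lumen_mask",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# Anatomical phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lobe:
    """An axis-aligned ellipsoid in physical (mm) coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError(f"ellipsoid semi-axes must be positive, got {self.semi_axes}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and degradation settings for one anatomical phantom.

    The grid is ``shape`` voxels with in-plane pixel ``pixel_size`` mm and
    axial center-to-center spacing ``thickness + gap`` mm.  ``lobes`` lists
    every ellipsoid explicitly (both hemispheres); their union is the CSF
    compartment.  ``blur_sigma`` (mm) stands in for partial-volume mixing,
    ``noise_sigma`` (a.u.) for acquisition noise.  Ventricle polarity follows
    from the two intensities: darker than background on T1/FLAIR-like images,
    brighter on T2*-like ones.
    """

    shape: tuple[int, int, int]
    pixel_size: float
    thickness: float
    gap: float
    lobes: tuple[Lobe, ...]
    ventricle_intensity: float = 20.0
    background_intensity: float = 120.0
    blur_sigma: float = 1.0
    noise_sigma: float = 8.0
    seed: int = 0
    oversample: int = 5

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValidationError(f"grid shape must be positive, got {self.shape}")
        if self.pixel_size <= 0:
            raise ValidationError(f"pixel size must be positive, got {self.pixel_size}")
        if self.thickness <= 0:
            raise ValidationError(f"slice thickness must be positive, got {self.thickness}")
        if self.gap < 0:
            raise ValidationError(f"slice gap must be nonnegative, got {self.gap}")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValidationError("blur and noise sigmas must be nonnegative")
        if self.ventricle_intensity == self.background_intensity:
            raise ValidationError("ventricle and background intensities must differ")
        if self.oversample < 5:
            raise ValidationError("oversample must be >= 5 (high-res grid at least 5x finer)")
        if not self.lobes:
            raise ValidationError("at least one lobe is required")
        ext = self.extent_mm
        for lobe in self.lobes:
            for c, a, e in zip(lobe.center, lobe.semi_axes, ext):
                if c - a < 0 or c + a > e:
                    raise ValidationError(
                        f"lobe {lobe} extends outside the grid (physical extent {ext} mm)"
                    )

    @property
    def slice_spacing(self) -> float:
        return self.thickness + self.gap

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.shape
        return (nx * self.pixel_size, ny * self.pixel_size, nz * self.slice_spacing)

    @property
    def polarity(self) -> str:
        """``"dark"`` if the ventricle is darker than background else ``"bright"``."""
        return "dark" if self.ventricle_intensity < self.background_intensity else "bright"


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated phantom.

    ``volume_ml`` is integrated on the fine pre-degradation grid;
    ``mask`` is the partial-volume-majority mask at acquisition resolution;
    ``area_cm2`` is the in-plane area of ``mask`` on ``reference_slice``.
    """

    volume_ml: float
    mask: VoiMask
    area_cm2: float
    reference_slice: int

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValidationError("truth volume must be positive")
        if self.mask.is_empty():
            raise ValidationError("truth mask must be nonempty")
        if self.area_cm2 <= 0:
            raise ValidationError("truth reference-slice area must be positive")

    def seed_points(self) -> list[tuple[int, int, int]]:
        """One voxel seed per connected component on the reference slice.

        Mimics the clinician's click inside each lateral ventricle: the
        centroid of each in-plane component, snapped to the nearest true
        voxel of that component.
        """
        sl = self.mask.data[:, :, self.reference_slice]
        labels, n = ndimage.label(sl)
        seeds = []
        for lab in range(1, n + 1):
            xs, ys = np.nonzero(labels == lab)
            cx, cy = xs.mean(), ys.mean()
            j = int(np.argmin((xs - cx) ** 2 + (ys - cy) ** 2))
            seeds.append((int(xs[j]), int(ys[j]), self.reference_slice))
        return seeds


def default_ventricle_spec(
    scale: float = 1.0,
    *,
    pixel_size: float = 1.0,
    thickness: float = 5.0,
    gap: float = 1.0,
    seed: int = 0,
    blur_sigma: float = 1.0,
    noise_sigma: float = 8.0,
    ventricle_intensity: float = 20.0,
    background_intensity: float = 120.0,
) -> PhantomSpec:
    """Two mirrored body+anterior-horn lobes, sized by a linear ``scale``.

    At ``scale=1`` the compartment is roughly 23 mL (small adult lateral
    ventricles); volume grows as ``scale**3``, so scales ``1..2.2`` span
    roughly the 20-250 mL range seen across vascular dementia, Alzheimer's
    disease and normal pressure hydrocephalus.  The grid is sized to the
    scaled geometry plus a 12 mm margin.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    s = scale
    # One hemisphere, in a local frame (mm); x = left-right offset from midline.
    # Bodies are elongated anterior-posterior and axially (lateral ventricles
    # span several axial slices even on gapped 2D acquisitions); the anterior
    # horns dip inferiorly.
    body_off, body_ax = (13.0 * s, 4.0 * s, 0.0), (6.5 * s, 22.0 * s, 14.0 * s)
    horn_off, horn_ax = (10.5 * s, -18.0 * s, -5.0 * s), (5.0 * s, 12.0 * s, 9.0 * s)
    margin = 12.0
    half_x = max(body_off[0] + body_ax[0], horn_off[0] + horn_ax[0]) + margin
    half_y = max(body_off[1] + body_ax[1], abs(horn_off[1]) + horn_ax[1]) + margin
    half_z = max(body_ax[2], horn_off[2] + horn_ax[2]) + margin
    spacing = thickness + gap
    nx = 2 * math.ceil(half_x / pixel_size)
    ny = 2 * math.ceil(half_y / pixel_size)
    nz = 2 * math.ceil(half_z / spacing)
    cx, cy, cz = nx * pixel_size / 2, ny * pixel_size / 2, nz * spacing / 2
    lobes = []
    for side in (-1.0, 1.0):
        for off, ax in ((body_off, body_ax), (horn_off, horn_ax)):
            lobes.append(Lobe((cx + side * off[0], cy + off[1], cz + off[2]), ax))
    return PhantomSpec(
        shape=(nx, ny, nz),
        pixel_size=pixel_size,
        thickness=thickness,
        gap=gap,
        lobes=tuple(lobes),
        ventricle_intensity=ventricle_intensity,
        background_intensity=background_intensity,
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _lobe_indicator(spec: PhantomSpec, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Boolean union-of-ellipsoids indicator on an open grid of coordinates."""
    x = xs[:, None, None]
    y = ys[None, :, None]
    z = zs[None, None, :]
    out = np.zeros((xs.size, ys.size, zs.size), dtype=bool)
    for lobe in spec.lobes:
        (cx, cy, cz), (a, b, c) = lobe.center, lobe.semi_axes
        out |= ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    return out


def _slab_layers(spec: PhantomSpec, z_hi: np.ndarray, k: int) -> np.ndarray:
    """Indices of fine z-layers whose centers fall inside slice ``k``'s excited slab."""
    center = (k + 0.5) * spec.slice_spacing
    half = spec.thickness / 2
    return np.nonzero((z_hi >= center - half) & (z_hi <= center + half))[0]


def make_ventricle_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Render, degrade and resample one anatomical phantom.

    The compartment is rasterised on a grid ``oversample`` times finer than
    the acquisition grid in all axes.  Ground truth volume is the fine-voxel
    count times the fine-voxel volume, computed before blur or noise.  The
    degraded image is Gaussian-blurred in mm units, block-averaged in-plane,
    slab-averaged through-plane over each excited 5 mm slab (the gap is never
    sampled — as acquired), then corrupted with additive Gaussian noise.
    """
    nx, ny, nz = spec.shape
    f = spec.oversample
    p_hi = spec.pixel_size / f
    # Fine axial step: an integer number of layers per center-to-center spacing,
    # at least `f` per spacing and no coarser than 1 mm for accurate slab averages.
    n_layers = max(f, math.ceil(spec.slice_spacing / 1.0))
    dz_hi = spec.slice_spacing / n_layers
    xs = (np.arange(nx * f) + 0.5) * p_hi
    ys = (np.arange(ny * f) + 0.5) * p_hi
    zs = (np.arange(nz * n_layers) + 0.5) * dz_hi

    indicator = _lobe_indicator(spec, xs, ys, zs)
    voxel_hi_mm3 = p_hi * p_hi * dz_hi
    volume_ml = float(indicator.sum()) * voxel_hi_mm3 / 1000.0
    if volume_ml <= 0:
        raise ValidationError("phantom geometry produced an empty compartment")

    # Acquisition-resolution truth mask: majority partial-volume fraction.
    frac = _resample_to_acquisition(indicator.astype(np.float32), spec, n_layers, zs)
    truth_mask = VoiMask(frac > 0.5, provenance="truth")
    if truth_mask.is_empty():
        raise ValidationError("truth mask empty at acquisition resolution")
    zc = np.nonzero(truth_mask.data)[2]
    ref_slice = int(math.floor(zc.mean()))
    area_cm2 = float(truth_mask.data[:, :, ref_slice].sum()) * spec.pixel_size**2 / 100.0

    img_hi = np.where(
        indicator, np.float32(spec.ventricle_intensity), np.float32(spec.background_intensity)
    )
    del indicator
    if spec.blur_sigma > 0:
        sigma_vox = (spec.blur_sigma / p_hi, spec.blur_sigma / p_hi, spec.blur_sigma / dz_hi)
        ndimage.gaussian_filter(img_hi, sigma=sigma_vox, output=img_hi, mode="nearest")
    img = _resample_to_acquisition(img_hi, spec, n_layers, zs)
    del img_hi
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)

    vol = ImageVolume(
        img,
        pixel_size=(spec.pixel_size, spec.pixel_size),
        thickness=spec.thickness,
        gap=spec.gap,
        meta={"seed": spec.seed, "polarity": spec.polarity},
    )
    truth = PhantomTruth(
        volume_ml=volume_ml, mask=truth_mask, area_cm2=area_cm2, reference_slice=ref_slice
    )
    return vol, truth


def _resample_to_acquisition(
    hi: np.ndarray, spec: PhantomSpec, n_layers: int, z_hi: np.ndarray
) -> np.ndarray:
    """Block-average in-plane (f x f) and slab-average through-plane."""
    nx, ny, nz = spec.shape
    f = spec.oversample
    inplane = hi.reshape(nx, f, ny, f, hi.shape[2]).mean(axis=(1, 3))
    out = np.empty((nx, ny, nz), dtype=np.float32)
    for k in range(nz):
        layers = _slab_layers(spec, z_hi, k)
        out[:, :, k] = inplane[:, :, layers].mean(axis=2)
    return out


# ---------------------------------------------------------------------------
# Flow phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowPhantomSpec:
    """A circular lumen with a periodic multi-harmonic flow waveform.

    ``harmonics`` are sine amplitudes ``A_k`` (mL/s) of the waveform
    ``Q(t) = sum_k A_k sin(2 pi k t / T)`` — zero-mean by construction, as a
    gated CSF flow curve is over one cardiac cycle.  Velocity is uniform over
    the lumen, ``v(t) = Q(t) / (pi r^2)``, and is encoded into image phase as
    ``phi = pi v / venc``.
    """

    radius: float  # mm
    harmonics: tuple[float, ...]  # mL/s
    period: float = 0.857  # s, ~70 bpm
    n_phases: int = 32
    venc: float = 10.0  # cm/s
    phase_noise_sigma: float = 0.0  # rad
    pixel_size: float = 0.25  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"lumen radius must be positive, got {self.radius}")
        if self.period <= 0:
            raise ValidationError(f"cardiac period must be positive, got {self.period}")
        if self.n_phases < 2:
            raise ValidationError(f"need >= 2 cardiac phases, got {self.n_phases}")
        if self.venc <= 0:
            raise ValidationError(f"venc must be positive, got {self.venc}")
        if self.phase_noise_sigma < 0:
            raise ValidationError("phase noise sigma must be nonnegative")
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be positive")
        if not self.harmonics:
            raise ValidationError("at least one harmonic amplitude is required")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Continuous flow rate Q(t) in mL/s."""
        t = np.asarray(t, dtype=float)
        q = np.zeros_like(t)
        for k, a in enumerate(self.harmonics, start=1):
            q += a * np.sin(2 * np.pi * k * t / self.period)
        return q

    @property
    def lumen_area_cm2(self) -> float:
        return math.pi * self.radius**2 / 100.0


def continuous_stroke_volume_ul(spec: FlowPhantomSpec, n_steps: int = 1_000_000) -> float:
    """Stroke volume of the continuous waveform, in ul per cardiac cycle.

    Mean of the positive- and negative-lobe integrals over one period,
    evaluated by midpoint quadrature on ``n_steps`` points.
    """
    t = (np.arange(n_steps) + 0.5) * spec.period / n_steps
    q = spec.waveform(t)
    dt = spec.period / n_steps
    v_pos = float(np.sum(np.maximum(q, 0.0)) * dt)
    v_neg = float(np.sum(np.maximum(-q, 0.0)) * dt)
    return (v_pos + v_neg) / 2.0 * 1000.0


def flow_lumen_mask(spec: FlowPhantomSpec, margin_mm: float = 4.0) -> np.ndarray:
    """Boolean lumen mask on the phantom's pixel grid (pixels whose centers lie inside)."""
    n = 2 * math.ceil((spec.radius + margin_mm) / spec.pixel_size) + 1
    c = n * spec.pixel_size / 2.0
    coords = (np.arange(n) + 0.5) * spec.pixel_size
    x = coords[:, None] - c
    y = coords[None, :] - c
    return x**2 + y**2 <= spec.radius**2


def make_flow_phantom(spec: FlowPhantomSpec) -> tuple[FlowSeries, float]:
    """Generate a velocity-encoded phase stack and its true stroke volume (ul).

    Cardiac phases sample the waveform at bin midpoints ``t_i = (i+0.5) T/n``.
    Refuses to alias: the peak continuous lumen velocity must stay below venc.
    """
    t_fine = np.linspace(0.0, spec.period, 4096, endpoint=False)
    v_peak = np.max(np.abs(spec.waveform(t_fine))) / spec.lumen_area_cm2
    if v_peak >= spec.venc:
        raise AliasingError(
            f"peak lumen velocity {v_peak:.2f} cm/s >= venc {spec.venc:.2f} cm/s; "
            "increase venc or reduce the waveform amplitude"
        )
    mask = flow_lumen_mask(spec)
    n = spec.n_phases
    t_i = (np.arange(n) + 0.5) * spec.period / n
    v_i = spec.waveform(t_i) / spec.lumen_area_cm2  # cm/s, uniform over lumen
    phases = np.zeros(mask.shape + (n,), dtype=np.float64)
    phases[mask, :] = np.pi * v_i / spec.venc
    if spec.phase_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        phases = phases + rng.normal(0.0, spec.phase_noise_sigma, size=phases.shape)
        np.clip(phases, -np.pi, np.pi, out=phases)
    series = FlowSeries(
        phases=phases,
        venc=spec.venc,
        pixel_size=(spec.pixel_size, spec.pixel_size),
        period=spec.period,
    )
    return series, continuous_stroke_volume_ul(spec)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Sample size and area moments (cm^2) for one diagnostic group."""

    n: int
    area_mean: float
    area_sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"each group needs n >= 2, got {self.n}")
        if self.area_sd < 0:
            raise ValidationError("area SD must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of paired (area, volume) values around a linear relation.

    Areas are drawn per group from a truncated normal supported where the
    linear relation yields nonnegative volumes (at the line's root when the
    slope is positive, else at zero) — mirroring a clinical cohort, in which
    every measured volume is positive.  Volumes follow
    ``slope * area + intercept`` plus Gaussian residual noise, floored at
    zero (volumes are physical; with the support truncation the floor only
    engages through rare noise excursions near the root).
    """

    groups: dict[str, GroupSpec]
    slope: float = 7.0  # mL per cm^2
    intercept: float = -61.0  # mL
    noise_sd: float = 10.0  # mL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("at least one group is required")
        if self.noise_sd < 0:
            raise ValidationError("residual noise SD must be nonnegative")
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValidationError("slope and intercept must be finite")


def dementia_cohort_spec(noise_sd: float = 10.0, seed: int = 0) -> CohortSpec:
    """The three-group dementia cohort used throughout: AD 19, NPH 13, VaD 13.

    Group area moments follow the study population (AD and VaD around
    16 cm^2, NPH around 34 cm^2 with a wide spread); the volume relation is
    the published 7 mL/cm^2 slope with -61 mL intercept.
    """
    return CohortSpec(
        groups={
            "AD": GroupSpec(19, 16.0, 6.0),
            "NPH": GroupSpec(13, 34.0, 18.0),
            "VaD": GroupSpec(13, 16.0, 5.0),
        },
        slope=7.0,
        intercept=-61.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table with columns ``group, lva_cm2, lvv_ml``."""
    rng = np.random.default_rng(spec.seed)
    lower = max(0.0, -spec.intercept / spec.slope) if spec.slope > 0 else 0.0
    rows = []
    for name in sorted(spec.groups):
        g = spec.groups[name]
        if g.area_sd == 0:
            lva = np.full(g.n, g.area_mean)
        else:
            a = (lower - g.area_mean) / g.area_sd
            lva = stats.truncnorm.rvs(
                a, np.inf, loc=g.area_mean, scale=g.area_sd, size=g.n, random_state=rng
            )
        noise = rng.normal(0.0, spec.noise_sd, size=g.n) if spec.noise_sd > 0 else 0.0
        lvv = np.maximum(spec.slope * lva + spec.intercept + noise, 0.0)
        rows.append(pd.DataFrame({"group": name, "lva_cm2": lva, "lvv_ml": lvv}))
    return pd.concat(rows, ignore_index=True)
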