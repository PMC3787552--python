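# Methods

`lvmorph` implements a complete, testable analogue of a clinical
lateral-ventricle morphometry workflow: semi-automatic 3D segmentation of the
lateral ventricles, gap-inclusive volumetry, single-slice area measurement, a
linear area-to-volume estimator with Bland–Altman validation, phase-contrast
CSF flow quantification, and the hydrodynamic quantities that govern
aqueductal flow.  Because no patient images ship with the package, every
stage is exercised on synthetic phantoms whose ground truth is known by
construction.  This note records the models, the parameters that matter, the
numerical choices, and what the phantoms do and do not establish about real
data.

## The segmentation model

Each axial slice is segmented in two stages, mirroring the semi-automatic
clinical procedure of contouring first and thresholding second.

**Stage 1 — region-based level set.**  A two-phase morphological Chan–Vese
evolution (`skimage.segmentation.morphological_chan_vese`) is grown from one
seed click per ventricle.  The criterion compares each pixel's squared
deviation from the two evolving region means, so it is driven purely by
intensity statistics and is exactly invariant under affine intensity
rescaling with positive gain — the same contour is found on differently
windowed images.  Of the converged foreground, only connected components
containing a seed are kept.  `iterations` (default 300; 400 for large
ventricles) bounds front growth at roughly one pixel per iteration and must
exceed the largest expected in-plane ventricle radius; `smoothing` (default
1) is the number of morphological curvature passes per iteration.

**Stage 2 — intra-VOI Otsu refinement.**  CSF compartments are bounded by a
partial-volume ramp: boundary voxels mix CSF and parenchyma intensities, and
a contour placed anywhere on the ramp is systematically biased.  The
refinement computes an Otsu threshold *on the gray levels inside the VOI
only* and keeps the sub-cluster matching the ventricle polarity (below the
threshold when CSF is dark, above when bright).  Two workflow choices matter
and were settled during development:

* The VOI handed to the threshold stage is the level-set contour **dilated by
  a surround shell**, sized per slice as `clip(ceil(area/perimeter), 4, 15)`
  pixels.  A shell of width ≈ area/perimeter contributes about as many
  pixels as the compartment interior, so the intra-VOI histogram is balanced
  and the Otsu threshold lands mid-ramp.  With a thin (or absent) shell the
  pure-CSF cluster dominates, the threshold is dragged toward it, and the
  mask systematically loses the legitimate half of the partial-volume ramp
  (we measured 10–25% volume underestimation).
* One threshold is computed for the **whole 3D VOI union**, not per slice.
  A per-slice threshold adapts to whatever weak contrast an end slice has
  and resurrects sub-half partial-volume footprints; the volume-wide
  threshold treats all slices consistently, which is also how a single
  threshold is chosen on a VOI histogram in the clinical tool.

Slice chaining: segmentation starts on the seeded slice and propagates in
both axial directions, seeding each next slice with the centroids of the
previous slice's refined components and initialising its level set from the
previous contour (point seeds regrow poorly on low-contrast end slices).
Propagation stops when no seed lands on ventricle-polarity tissue or the
contour collapses.  Components touching the slice border (background
leak-through) and speckles under `min_component_px` (default 4 px) are
discarded.

The Otsu operator itself is implemented over the *observed* gray levels
(classes `{x <= t}` / `{x > t}`, between-class variance `w0 w1 (mu0-mu1)^2`,
ties broken toward the smallest level), which makes it well defined on
floating-point images; a 256-bin mode mirrors 8-bit histogram practice.
Property tests check it against exhaustive search.

## Volumetry and the reference slice

Volumes count mask voxels times `dx * dy * (thickness + gap)`: on gapped 2D
acquisitions the unsampled CSF between excited slabs is attributed to the
adjacent slices, as in routine clinical volumetry.  The axial spacing
convention follows the usual FLAIR prescription of a 5 mm slab with a 6 mm
center-to-center spacing, i.e. thickness 5 mm + gap 1 mm; both numbers are
explicit, independent fields everywhere.

The 2D area is measured on a single axial reference slice.  Clinically that
plane is set on a sagittal scout through the anterior horns and bodies;
phantoms have no sagittal anatomy, so the package offers an explicit slice
index (primary, mirroring the clinician) and a documented `auto` mode that
takes the slice containing the mask centroid (floor on ties) for
reproducible tests.  Per-sequence measurements are combined by arithmetic
mean, as when averaging two 3D volume estimates or two 2D area estimates per
patient.

## The area-to-volume estimator

The headline model is the linear relation

    LvV (mL) = 7 * LvA (cm^2) - 61

exposed verbatim as `PUBLISHED_MODEL` and never overwritten by fits.
`AreaVolumeModel.fit()` estimates the same line from paired data by ordinary
least squares (statsmodels), reporting slope/intercept with 95% confidence
intervals, OLS R², residual SD, and — separately, never conflated —
Spearman's rho.  Agreement between two volume measurements uses
Bland–Altman: bias = mean difference, limits = bias ± 1.96 · SD with the
sample (n−1) SD.  The 1.96 normal quantile is fixed rather than t-based, the
standard presentation; about 95% of differences fall inside the limits, and
a Monte-Carlo test verifies that convention.

Negative estimates (areas below the line's root at 61/7 ≈ 8.71 cm²) are
returned as-is with a warning: they flag model extrapolation, and silently
clamping them would hide it.

## Flow quantification

A gated phase-contrast series encodes through-plane velocity in the image
phase, `v = venc * phi / pi`, so ±π maps to ±venc; out-of-range phases are
rejected rather than unwrapped.  The per-cardiac-phase flow rate is the ROI
sum of velocities times pixel area (cm/s × cm² = mL/s).  Stroke volume is
the mean of the positive- and negative-lobe integrals of that curve over one
cycle, in µl; integration is the midpoint rule with uniform Δt = T/n
(retrospective gating assumed uniform), whose error on smooth waveforms is
O(n⁻²) — about 0.1% at 32 phases.  The negative lobe enters by magnitude,
so the stroke volume is invariant under sign-convention flips, and no
eddy-current baseline subtraction is applied by default (an optional
static-ROI subtraction flag exists but defaults off).

## Hydrodynamics

The discussion-level physics is implemented in SI units with explicit
fields: the Womersley number `Wo = d_h * sqrt(rho * omega / mu)` (with `d_h`
the hydraulic *diameter*; any self-consistent unit system gives the same
dimensionless value), Hagen–Poiseuille flow `Q = pi R^4 dP / (8 eta L)`, and
the duct's hydraulic resistance `8 eta L / (pi R^4)` — named `R_hyd` to
avoid collision with the Reynolds number.  Flow and resistance are exact
inverses through the pressure drop, which a 1000-draw property test checks
to machine precision.

## The synthetic phantoms

**Anatomy.**  A phantom is a union of mirrored ellipsoid pairs ("body" +
"anterior horn" per hemisphere) rasterised on a grid at least 5× finer than
the acquisition grid in every axis.  Ground truth (volume, acquisition-grid
majority mask, reference-slice area) is computed on the fine grid *before*
degradation, so it is independent of blur and noise settings by
construction.  The degraded image is Gaussian-blurred (σ in mm, the
partial-volume surrogate), averaged in-plane per pixel and through-plane
over each excited 5 mm slab (the gap is never sampled, as acquired), then
corrupted with additive Gaussian noise.  Gaussian rather than Rician noise
is deliberate: at the contrasts used (default 100 a.u. contrast, 8 a.u.
noise, CNR 12.5) the Rician correction is negligible and the Gaussian model
stays analytically tractable.  Polarity is derived from the two intensity
fields (CSF dark on T1/FLAIR-like images, bright on T2*-like), making an
inconsistent polarity/intensity pair unrepresentable.

`default_ventricle_spec(scale)` sizes a realistic two-lobe geometry by a
linear factor: volume grows as `scale³`, with scales 1.0–2.35 spanning
roughly 20–260 mL — small-dementia through hydrocephalic ventricles.  The
default grid is 1 mm in-plane.  Ten such phantoms, segmented end to end,
recover their true volumes within ±5% (measured max 4.2%) and take about
two minutes in total; this batch size keeps the whole suite comfortably
fast while covering the clinical size range.

**Flow.**  The flow phantom is a circular lumen carrying a zero-mean
multi-harmonic waveform `Q(t) = Σ A_k sin(2πkt/T)` with spatially uniform
velocity `v = Q/(πr²)` encoded into phase.  Generation refuses to alias
(peak velocity must stay below venc).  The true stroke volume is evaluated
on the continuous waveform by 10⁶-step midpoint quadrature (deterministic;
equal to A·T/π for a single harmonic).  Lumen pixelisation perturbs the
decoded flow by the relative error of the pixel-counted disk area; at the
default radius/pixel ratio of 25 this is ≈0.1–0.6%, so closed-form checks at
the 1% level probe the method, not the raster.

**Cohorts.**  Paired (area, volume) tables emulate a three-group
dementia/hydrocephalus population: group sizes 19/13/13 with area moments
16 ± 6, 34 ± 18 and 16 ± 5 cm², volumes on the published line plus Gaussian
residual noise (default SD 10 mL), floored at zero.  Areas are drawn from a
normal truncated at the line's root (8.71 cm²) rather than at zero: in a
real cohort every measured volume is positive, and truncating only at zero
lets the floor bind for ~11% of draws, which attenuates any fitted slope —
an artefact of the generator, not of the estimator under study.  With the
root truncation the floor engages in fewer than one row per 45-subject
cohort and the OLS confidence intervals cover the generating parameters at
close to their nominal rate.

**What the phantoms do not show.**  They contain no skull, sulci, choroid
plexus, third/fourth ventricle, bias field, or k-space artefacts; their
boundaries are smooth ellipsoid unions; flow is spatially uniform rather
than a Womersley profile; noise is stationary Gaussian.  Passing tests
therefore establish the correctness of the *computational* pipeline —
geometry handling, thresholding behaviour on partial-volume ramps,
integration conventions, statistical procedures — not clinical accuracy on
patient images, where tissue heterogeneity, motion and operator variability
dominate.

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed per generator call
  (`numpy.random.default_rng`); identical specs give bit-identical outputs.
* Otsu ties break toward the smallest candidate level; a constant histogram
  raises a dedicated error, except inside `refine_voi`, where a
  constant-intensity VOI is returned unrefined with a logged warning (there
  is no contrast to refine).
* The reference-slice `auto` mode floors the centroid on ties.
* Raw doubles are preserved in all outputs; nothing is rounded internally.
* Images with missing or nonpositive header spacing are rejected outright —
  isotropy is never silently assumed.
* Pipeline outputs embed the config hash and seed; re-running with the same
  config reproduces results value-for-value, and per-subject failures are
  recorded as error rows without aborting the batch.  Config files are
  validated with pydantic models.

## Known limitations

* The level-set stage assumes the compartment is the connected
  intensity-coherent region around the seed; heavily septated or
  artefact-bridged ventricles would need manual re-seeding per slice.
* The reference-plane `auto` mode is a phantom-testing surrogate; clinical
  use requires the explicit anatomically chosen index.
* The published coefficients encode human ventricle allometry; phantom
  geometries have their own area-volume relation, so end-to-end phantom
  tests fit the line to the phantom cohort rather than asserting the human
  coefficients.
* Stroke-volume accuracy degrades if the lumen is only a few pixels wide
  (pixelised-area error) or if flow aliases; the generator refuses the
  latter and documents the former.
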