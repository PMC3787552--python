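"""Generators: geometry truth, degradation independence, determinism."""

import numpy as np
import pytest

from lvmorph import (
    AliasingError,
    CohortSpec,
    FlowPhantomSpec,
    GroupSpec,
    Lobe,
    PhantomSpec,
    ValidationError,
    default_ventricle_spec,
    dementia_cohort_spec,
    make_cohort,
    make_flow_phantom,
    make_ventricle_phantom,
)
from lvmorph.phantom import continuous_stroke_volume_ul


def sphere_spec(**overrides):
    kw = dict(
        shape=(48, 48, 8),
        pixel_size=1.0,
        thickness=5.0,
        gap=1.0,
        lobes=(Lobe((24.0, 24.0, 24.0), (10.0, 10.0, 10.0)),),
        blur_sigma=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


class TestVentriclePhantom:
    def test_sphere_volume_matches_closed_form(self):
        vol, truth = make_ventricle_phantom(sphere_spec())
        expected = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0  # mL
        assert truth.volume_ml == pytest.approx(expected, rel=5e-3)

    def test_determinism(self):
        spec = default_ventricle_spec(1.1, seed=42)
        v1, t1 = make_ventricle_phantom(spec)
        v2, t2 = make_ventricle_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(t1.mask.data, t2.mask.data)
        assert t1.volume_ml == t2.volume_ml
        assert t1.area_cm2 == t2.area_cm2

    def test_two_lobe_truth_matches_independent_voxel_count(self):
        """Truth volume equals a brute-force indicator integration coded here
        on its own grid (0.4 mm steps)."""
        spec = default_ventricle_spec(1.0, seed=0)
        _, truth = make_ventricle_phantom(spec)
        step = 0.4
        ex, ey, ez = spec.extent_mm
        xs = np.arange(step / 2, ex, step)
        ys = np.arange(step / 2, ey, step)
        zs = np.arange(step / 2, ez, step)
        inside = np.zeros((xs.size, ys.size, zs.size), dtype=bool)
        for lobe in spec.lobes:
            (cx, cy, cz), (a, b, c) = lobe.center, lobe.semi_axes
            inside |= (
                ((xs[:, None, None] - cx) / a) ** 2
                + ((ys[None, :, None] - cy) / b) ** 2
                + ((zs[None, None, :] - cz) / c) ** 2
            ) <= 1.0
        oracle_ml = inside.sum() * step**3 / 1000.0
        assert truth.volume_ml == pytest.approx(oracle_ml, rel=5e-3)

    def test_truth_invariant_to_blur_and_noise(self):
        base = default_ventricle_spec(1.2, seed=5, blur_sigma=0.0, noise_sigma=0.0)
        degraded = default_ventricle_spec(1.2, seed=5, blur_sigma=1.5, noise_sigma=12.0)
        _, t_clean = make_ventricle_phantom(base)
        _, t_deg = make_ventricle_phantom(degraded)
        assert t_clean.volume_ml == t_deg.volume_ml
        np.testing.assert_array_equal(t_clean.mask.data, t_deg.mask.data)

    def test_truth_volume_stable_under_pixel_size_halving(self):
        fine = sphere_spec(shape=(96, 96, 8), pixel_size=0.5)
        coarse = sphere_spec(shape=(48, 48, 8), pixel_size=1.0)
        _, tf = make_ventricle_phantom(fine)
        _, tc = make_ventricle_phantom(coarse)
        assert tf.volume_ml == pytest.approx(tc.volume_ml, rel=1e-2)

    def test_reference_area_matches_truth_mask_slice(self):
        spec = default_ventricle_spec(1.3, seed=2)
        _, truth = make_ventricle_phantom(spec)
        n_px = truth.mask.data[:, :, truth.reference_slice].sum()
        assert truth.area_cm2 == pytest.approx(n_px * spec.pixel_size**2 / 100.0)

    def test_lobe_outside_grid_rejected(self):
        with pytest.raises(ValidationError, match="outside the grid"):
            sphere_spec(lobes=(Lobe((5.0, 24.0, 24.0), (10.0, 10.0, 10.0)),))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            sphere_spec(pixel_size=-1.0)
        with pytest.raises(ValidationError):
            sphere_spec(thickness=0.0)
        with pytest.raises(ValidationError):
            default_ventricle_spec(0.0)


class TestFlowPhantom:
    def test_sinusoid_closed_form(self):
        """A pure sinusoid of amplitude A displaces A*T/pi per cycle."""
        spec = FlowPhantomSpec(radius=3.0, harmonics=(0.2,), period=0.8, venc=10.0)
        _, sv = make_flow_phantom(spec)
        assert sv == pytest.approx(0.2 * 0.8 / np.pi * 1000.0, rel=1e-4)

    def test_zero_amplitude_gives_zero_stroke_volume(self):
        spec = FlowPhantomSpec(radius=3.0, harmonics=(0.0,), venc=10.0)
        _, sv = make_flow_phantom(spec)
        assert sv == 0.0

    def test_two_harmonic_matches_fine_quadrature_oracle(self):
        spec = FlowPhantomSpec(radius=2.0, harmonics=(0.12, -0.05), period=0.9, venc=10.0)
        _, sv = make_flow_phantom(spec)
        # independent trapezoid quadrature on a dense grid
        t = np.linspace(0.0, spec.period, 2_000_001)
        q = spec.waveform(t)
        v_pos = np.trapezoid(np.maximum(q, 0.0), t)
        v_neg = np.trapezoid(np.maximum(-q, 0.0), t)
        oracle = (v_pos + v_neg) / 2.0 * 1000.0
        assert sv == pytest.approx(oracle, rel=1e-5)

    def test_aliasing_refused(self):
        # peak velocity = A / (pi r^2 / 100) = 10.2 cm/s > venc
        with pytest.raises(AliasingError, match="venc"):
            make_flow_phantom(
                FlowPhantomSpec(radius=2.5, harmonics=(2.0,), venc=10.0)
            )

    def test_net_volume_vanishes_for_zero_mean_waveform(self):
        spec = FlowPhantomSpec(radius=3.0, harmonics=(0.15, 0.04, -0.02), venc=10.0)
        series, _ = make_flow_phantom(spec)
        t = (np.arange(spec.n_phases) + 0.5) * spec.period / spec.n_phases
        net_ml = np.sum(spec.waveform(t)) * spec.period / spec.n_phases
        assert abs(net_ml) < 1e-6

    def test_determinism_with_noise(self):
        spec = FlowPhantomSpec(radius=3.0, harmonics=(0.1,), venc=10.0,
                               phase_noise_sigma=0.05, seed=9)
        s1, _ = make_flow_phantom(spec)
        s2, _ = make_flow_phantom(spec)
        np.testing.assert_array_equal(s1.phases, s2.phases)

    def test_continuous_quadrature_matches_sinusoid_closed_form(self):
        spec = FlowPhantomSpec(radius=3.0, harmonics=(np.pi,), period=1.0, venc=100.0)
        assert continuous_stroke_volume_ul(spec) == pytest.approx(1000.0, rel=1e-9)


class TestCohort:
    def test_noiseless_cohort_lies_exactly_on_line(self):
        spec = CohortSpec(
            groups={"g": GroupSpec(50, 20.0, 4.0)}, slope=7.0, intercept=-61.0,
            noise_sd=0.0, seed=3,
        )
        df = make_cohort(spec)
        np.testing.assert_allclose(df.lvv_ml, 7.0 * df.lva_cm2 - 61.0, rtol=0, atol=1e-12)

    def test_determinism(self):
        s = dementia_cohort_spec(seed=11)
        assert make_cohort(s).equals(make_cohort(s))

    def test_residual_sd_recovers_noise_sd(self):
        spec = CohortSpec(
            groups={"g": GroupSpec(10_000, 20.0, 4.0)}, noise_sd=5.0, seed=3
        )
        df = make_cohort(spec)
        resid = df.lvv_ml - (7.0 * df.lva_cm2 - 61.0)
        assert resid.std(ddof=1) == pytest.approx(5.0, rel=0.05)

    def test_group_sizes_and_columns(self):
        df = make_cohort(dementia_cohort_spec(seed=0))
        assert list(df.columns) == ["group", "lva_cm2", "lvv_ml"]
        assert df.groupby("group").size().to_dict() == {"AD": 19, "NPH": 13, "VaD": 13}
        assert (df.lvv_ml >= 0).all() and (df.lva_cm2 > 0).all()

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError, match="n >= 2"):
            GroupSpec(1, 16.0, 6.0)
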