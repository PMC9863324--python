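"""Phantom generator: analytic truth, determinism, mask/noise separation."""

from dataclasses import replace

import numpy as np
import pytest

from aortamech.phantom import (
    PhantomConfig,
    TensileSimConfig,
    ellipse_perimeter_ramanujan,
    generate_phantom,
    generate_tensile,
    piecewise_linear_stress,
    pulsation_waveform,
    sample_cohort,
)


class TestWaveform:
    def test_single_peak_with_exact_extrema_on_frames(self):
        s = pulsation_waveform(30)
        assert s[0] == 0.0
        assert s.max() == pytest.approx(1.0)
        # one contiguous rise then one contiguous fall
        d = np.diff(s)
        peak = np.argmax(s)
        assert np.all(d[:peak] > 0) and np.all(d[peak:] < 0)

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            pulsation_waveform(1)


class TestGeneratePhantom:
    def test_zero_pulsation_gives_static_truth(self):
        cfg = PhantomConfig(grid_size=64, n_frames=4, semi_axes_dia=(12, 10),
                            pulsation_fraction=0.0, center_offset_px=(0, 0), seed=1)
        _, masks, truth = generate_phantom(cfg)
        assert truth.true_compliance == 0.0
        assert truth.true_strain == 0.0
        assert all(np.array_equal(masks.frames[0], f) for f in masks.frames)

    def test_circle_mask_area_matches_pi_r_squared(self):
        # a = b = 20 mm at 1 mm/px: pixel count within 1% of pi * 20^2
        cfg = PhantomConfig(grid_size=128, n_frames=2, pixel_spacing=1.0,
                            semi_axes_dia=(20, 20), pulsation_fraction=0.0,
                            tilt_deg=0.0, center_offset_px=(0, 0), seed=0)
        _, masks, truth = generate_phantom(cfg)
        pixel_area = masks.frames[0].sum()
        assert pixel_area == pytest.approx(np.pi * 400, rel=0.01)
        assert truth.area_per_frame[0] == pytest.approx(np.pi * 400, rel=1e-12)

    def test_uniform_scaling_strain_equals_pulsation_fraction(self):
        # circular lumen, 10% radial pulsation: strain = (2pi*22 - 2pi*20)/(2pi*20)
        cfg = PhantomConfig(grid_size=128, n_frames=6, pixel_spacing=1.0,
                            semi_axes_dia=(20, 20), pulsation_fraction=0.1,
                            center_offset_px=(0, 0), seed=0)
        _, _, truth = generate_phantom(cfg)
        assert truth.true_strain == pytest.approx(0.1, rel=1e-9)

    def test_mask_area_within_1p5_percent_of_analytic(self, default_phantom):
        cfg, _, masks, truth = default_phantom
        px_area = cfg.pixel_spacing**2
        for k in range(cfg.n_frames):
            measured = masks.frames[k].sum() * px_area
            assert measured == pytest.approx(truth.area_per_frame[k], rel=0.015)

    def test_truth_compliance_self_consistent(self, default_phantom):
        cfg, _, _, truth = default_phantom
        recomputed = (truth.area_per_frame.max() - truth.area_per_frame.min()) / (
            cfg.pressures[0] - cfg.pressures[1]
        )
        assert truth.true_compliance == recomputed

    def test_seed_determinism(self):
        cfg = PhantomConfig(grid_size=64, n_frames=3, semi_axes_dia=(12, 10), seed=9)
        a = generate_phantom(cfg)
        b = generate_phantom(cfg)
        assert np.array_equal(a[0].frames, b[0].frames)
        assert np.array_equal(a[1].frames, b[1].frames)

    def test_artifacts_touch_intensities_not_masks(self, small_phantom):
        cfg, seq, masks, truth = small_phantom
        noisy_cfg = replace(cfg, artifact_level=0.9, noise_sd=0.3)
        seq2, masks2, truth2 = generate_phantom(noisy_cfg)
        assert np.array_equal(masks.frames, masks2.frames)
        assert truth2.true_compliance == truth.true_compliance
        assert not np.array_equal(seq.frames, seq2.frames)

    def test_vessel_exceeding_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds grid"):
            PhantomConfig(grid_size=64, semi_axes_dia=(40, 40))

    def test_quadrant_truth_sums_to_totals(self, default_phantom):
        _, _, _, truth = default_phantom
        area_sum = sum(truth.quadrant_areas.values())
        assert np.allclose(area_sum, truth.area_per_frame, rtol=1e-9)
        arc_sum = sum(truth.quadrant_arcs.values())
        assert np.allclose(arc_sum, truth.outer_perimeter_per_frame, rtol=1e-4)

    def test_cohort_sampler_varies_geometry_deterministically(self):
        a = sample_cohort(5, seed=4)
        b = sample_cohort(5, seed=4)
        assert a == b
        spacings = {c.pixel_spacing for c in a}
        assert len(spacings) == 5
        assert all(1.09 <= s <= 1.25 for s in spacings)


class TestRamanujanPerimeter:
    def test_circle_exact(self):
        assert ellipse_perimeter_ramanujan(10, 10) == pytest.approx(2 * np.pi * 10)

    def test_against_numerical_integration(self):
        from scipy.integrate import quad

        a, b = 28.0, 24.0
        integrand = lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
        exact, _ = quad(integrand, 0, 2 * np.pi)
        assert ellipse_perimeter_ramanujan(a, b) == pytest.approx(exact, rel=1e-9)


class TestGenerateTensile:
    def test_linear_record_inverts_exactly(self):
        cfg = TensileSimConfig(modulus_segments=(((0.0, 0.3), 0.5),), strain_max=0.3)
        rec = generate_tensile(cfg)
        strain = rec.displacement_mm / cfg.l0
        stress = rec.force_n / rec.a0
        assert np.allclose(stress, 0.5 * strain)

    def test_force_at_known_stress(self):
        # sigma = 0.1 MPa over A0 = 15 mm * 2 mm = 30 mm^2 -> F = 3 N
        cfg = TensileSimConfig(modulus_segments=(((0.0, 0.2), 0.5),), strain_max=0.2,
                               n_samples=3)
        rec = generate_tensile(cfg)
        assert rec.a0 == 30.0
        stress = piecewise_linear_stress(np.array([0.2]), cfg)[0]
        assert stress == pytest.approx(0.1)
        assert rec.force_n[-1] == pytest.approx(3.0)

    def test_piecewise_stress_continuous_at_breakpoints(self):
        cfg = TensileSimConfig()
        eps = np.array([0.1 - 1e-9, 0.1 + 1e-9])
        lo, hi = piecewise_linear_stress(eps, cfg)
        assert hi - lo < 1e-8

    def test_noise_seeded(self):
        cfg = TensileSimConfig(noise_sd=0.01, seed=7)
        assert np.array_equal(generate_tensile(cfg).force_n, generate_tensile(cfg).force_n)

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            TensileSimConfig(modulus_segments=())

    def test_non_contiguous_segments_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            TensileSimConfig(modulus_segments=(((0.0, 0.1), 0.3), ((0.2, 0.3), 1.0)))
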