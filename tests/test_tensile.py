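"""Stress-strain analysis: exact formulas, modulus recovery, window logic."""

import numpy as np
import pytest

from aortamech.io import PressurePair
from aortamech.phantom import TensileSimConfig, generate_tensile
from aortamech.tensile import (
    StressStrainCurve,
    TensileRecord,
    engineering_strain,
    engineering_stress,
    hoop_stress_mpa,
    load_tensile_csv,
    max_youngs_modulus,
    modulus_curve,
    physiological_youngs_modulus,
    save_tensile_csv,
    stress_strain_curve,
    trim_preconditioning,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "l, l0, expected", [(11, 10, 0.1), (10, 10, 0.0), (15, 10, 0.5)]
    )
    def test_engineering_strain(self, l, l0, expected):
        assert engineering_strain(l, l0) == pytest.approx(expected)

    def test_engineering_stress(self):
        assert engineering_stress(3.0, 30.0) == pytest.approx(0.1)  # MPa
        assert engineering_stress(0.0, 30.0) == 0.0

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            engineering_strain(10, 0)
        with pytest.raises(ValueError):
            engineering_stress(1.0, -1)

    def test_reference_area_from_sample_geometry(self):
        # 15 mm square sample, 2 mm wall: A0 = 30 mm^2
        rec = TensileRecord(np.array([0.0, 1.0]), np.array([0.0, 1.0]), l0=15, thickness=2)
        assert rec.a0 == 30.0

    def test_hoop_stress(self):
        # 120 mmHg, r 20 mm, t 2 mm -> 0.160 MPa
        assert hoop_stress_mpa(120, 20, 2) == pytest.approx(0.160, abs=5e-4)


class TestStressStrainCurve:
    def test_linear_record_lies_on_line(self):
        rec = generate_tensile(
            TensileSimConfig(modulus_segments=(((0.0, 0.3), 0.5),), strain_max=0.3)
        )
        curve = stress_strain_curve(rec)
        assert np.allclose(curve.stress, 0.5 * curve.strain)

    def test_zero_force_zero_stress(self):
        rec = TensileRecord(np.linspace(0, 5, 20), np.zeros(20))
        assert np.all(stress_strain_curve(rec).stress == 0)

    def test_duplicate_strains_collapsed_by_mean(self):
        rec = TensileRecord(
            np.array([0.0, 1.0, 1.0, 2.0]), np.array([0.0, 2.0, 4.0, 6.0]), l0=10, thickness=3
        )
        curve = stress_strain_curve(rec)
        assert len(curve.strain) == 3
        assert curve.stress[1] == pytest.approx(3.0 / 30.0)

    def test_all_duplicates_raises(self):
        rec = TensileRecord(np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            stress_strain_curve(rec)

    def test_roundtrip_slope_recovery(self):
        """Least-squares slope of the noiseless simulated curve is E within 1%."""
        rec = generate_tensile(
            TensileSimConfig(modulus_segments=(((0.0, 0.2), 0.5),), strain_max=0.2)
        )
        curve = stress_strain_curve(rec)
        slope = np.polyfit(curve.strain, curve.stress, 1)[0]
        assert slope == pytest.approx(0.5, rel=0.01)


class TestModulus:
    def test_linear_constant_everywhere(self):
        curve = StressStrainCurve(np.linspace(0, 0.3, 100), 0.5 * np.linspace(0, 0.3, 100))
        res = modulus_curve(curve, smoothing_window=1)
        assert np.allclose(res.modulus, 0.5, rtol=1e-9)
        assert max_youngs_modulus(res) == pytest.approx(0.5)

    def test_quadratic_derivative(self):
        eps = np.linspace(0, 1, 200)
        res = modulus_curve(StressStrainCurve(eps, eps**2), smoothing_window=1)
        interior = slice(2, -2)
        assert np.allclose(res.modulus[interior], 2 * eps[interior], atol=0.02)

    def test_bilinear_max_is_stiff_branch(self):
        rec = generate_tensile(TensileSimConfig())  # 0.3 then 1.2 MPa segments
        res = modulus_curve(stress_strain_curve(rec), smoothing_window=1)
        assert max_youngs_modulus(res) == pytest.approx(1.2, rel=0.02)

    def test_noisy_recovery_within_2_percent(self):
        rec = generate_tensile(
            TensileSimConfig(
                modulus_segments=(((0.0, 0.3), 0.5),), strain_max=0.3,
                n_samples=300, noise_sd=0.005, seed=11,
            )
        )
        res = modulus_curve(stress_strain_curve(rec), smoothing_window=11)
        interior = slice(10, -10)  # smoothing pads the edges
        assert res.modulus[interior].mean() == pytest.approx(0.5, rel=0.02)

    def test_secant_mode(self):
        eps = np.linspace(0, 0.3, 50)
        res = modulus_curve(StressStrainCurve(eps, 0.7 * eps), smoothing_window=1, mode="secant")
        assert np.allclose(res.modulus[1:], 0.7, rtol=1e-9)
        assert res.modulus[0] == 0.0

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            modulus_curve(StressStrainCurve(np.array([0.0, 0.1]), np.array([0.0, 0.1])))


class TestPhysiologicalModulus:
    def setup_method(self):
        self.pp = PressurePair(120, 80)

    def test_linear_curve_window_independent(self):
        eps = np.linspace(0, 0.4, 400)
        res = modulus_curve(StressStrainCurve(eps, 0.8 * eps), smoothing_window=1)
        e_phys = physiological_youngs_modulus(res, self.pp, radius_mm=20, wall_thickness_mm=2)
        assert e_phys == pytest.approx(0.8, rel=1e-6)

    def test_window_inside_soft_branch(self):
        # soft branch up to eps 0.5 reaches 0.5*0.4=0.2 MPa > sigma(120 mmHg)=0.16
        cfg = TensileSimConfig(
            modulus_segments=(((0.0, 0.5), 0.4), ((0.5, 0.8), 2.0)), strain_max=0.8,
            n_samples=800,
        )
        res = modulus_curve(stress_strain_curve(generate_tensile(cfg)), smoothing_window=1)
        e_phys = physiological_youngs_modulus(res, self.pp, 20, 2)
        assert e_phys == pytest.approx(0.4, rel=0.02)

    def test_e_phys_never_exceeds_e_max(self):
        for seed in range(5):
            cfg = TensileSimConfig(noise_sd=0.003, seed=seed)
            res = modulus_curve(stress_strain_curve(generate_tensile(cfg)), 11)
            e_phys = physiological_youngs_modulus(res, self.pp, 20, 2)
            assert e_phys <= max_youngs_modulus(res) + 1e-12

    def test_empty_window_raises_actionable_error(self):
        eps = np.linspace(0, 0.01, 10)  # curve never reaches the window
        res = modulus_curve(StressStrainCurve(eps, 0.01 * eps), smoothing_window=1)
        with pytest.raises(ValueError, match="physiological window"):
            physiological_youngs_modulus(res, self.pp, 20, 2)


class TestScalingProperties:
    def test_doubling_force_doubles_stress_and_modulus(self):
        disp = np.linspace(0, 3, 50)
        force = np.linspace(0, 6, 50)
        r1 = TensileRecord(disp, force)
        r2 = TensileRecord(disp, 2 * force)
        m1 = modulus_curve(stress_strain_curve(r1), 1)
        m2 = modulus_curve(stress_strain_curve(r2), 1)
        assert max_youngs_modulus(m2) == pytest.approx(2 * max_youngs_modulus(m1))

    def test_doubling_l0_doubles_tangent_modulus(self):
        disp = np.linspace(0, 3, 50)
        force = np.linspace(0, 6, 50)
        m1 = modulus_curve(stress_strain_curve(TensileRecord(disp, force, l0=10, thickness=2)), 1)
        # doubled rest length at constant A0 (thickness halved): same stresses,
        # halved strains, so the tangent modulus doubles
        m2 = modulus_curve(stress_strain_curve(TensileRecord(disp, force, l0=20, thickness=1)), 1)
        assert max_youngs_modulus(m2) == pytest.approx(2 * max_youngs_modulus(m1))


class TestPreconditioningAndIO:
    def test_trim_preconditioning_finds_last_zero_return(self):
        # two small cycles then the final pull
        disp = np.concatenate([np.linspace(0, 2, 10), np.linspace(2, 4, 10), np.linspace(4, 10, 20)])
        force = np.concatenate([np.abs(np.sin(np.linspace(0, np.pi, 10))),
                                np.abs(np.sin(np.linspace(0, np.pi, 10))),
                                np.linspace(0, 5, 20)])
        d, f = trim_preconditioning(disp, force, force_floor_n=0.05)
        assert d[0] == 0.0
        assert f[0] <= 0.05
        assert len(d) == 20  # exactly the final pull (its first sample is the zero return)

    def test_csv_roundtrip(self, tmp_path):
        rec = generate_tensile(TensileSimConfig(noise_sd=0.002, seed=3))
        path = save_tensile_csv(rec, tmp_path / "sample.csv")
        back = load_tensile_csv(path)
        assert np.allclose(back.displacement_mm, rec.displacement_mm)
        assert np.allclose(back.force_n, rec.force_n)
        assert back.l0 == rec.l0 and back.thickness == rec.thickness
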