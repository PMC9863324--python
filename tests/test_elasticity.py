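"""Compliance, strain, quadrant partition: formulas, oracles, invariants."""

import numpy as np
import pytest

from aortamech.elasticity import (
    AreaCurve,
    PerimeterCurve,
    QUADRANT_ORDER,
    area_curve,
    centroid,
    elasticity_report,
    global_compliance,
    global_strain,
    local_compliance,
    local_strain,
    partition_quadrants,
    perimeter_curve,
)
from aortamech.io import MaskSequence, PressurePair
from tests.conftest import make_disk


def as_masks(frames, spacing=1.0):
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return MaskSequence(frames=frames.astype(np.uint8), pixel_spacing=(spacing, spacing))


class TestCentroid:
    def test_symmetric_disk(self):
        c = centroid(make_disk(128, (63.5, 63.5), 30))
        assert c == pytest.approx((63.5, 63.5), abs=0.5)

    def test_single_pixel(self):
        m = np.zeros((30, 30), bool)
        m[10, 20] = True
        assert centroid(m) == (10.0, 20.0)

    def test_two_pixel_mean(self):
        m = np.zeros((20, 20), bool)
        m[0, 0] = m[10, 10] = True
        assert centroid(m) == (5.0, 5.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((5, 5), bool))


class TestAreaCurve:
    def test_pixel_count_times_spacing(self):
        m = np.zeros((30, 30), bool)
        m[5:15, 5:15] = True  # 100 px
        curve = area_curve(as_masks(m, spacing=1.25))
        assert curve.total[0] == pytest.approx(100 * 1.25**2)

    def test_circle_area_oracle(self):
        m = make_disk(128, (63.5, 63.5), 20)
        curve = area_curve(as_masks(m))
        assert curve.total[0] == pytest.approx(np.pi * 400, rel=0.01)

    def test_quadrants_sum_exactly(self, disk_mask):
        curve = area_curve(as_masks(disk_mask))
        total_from_quadrants = sum(q[0] for q in curve.per_quadrant.values())
        assert total_from_quadrants == curve.total[0]

    def test_empty_frame_raises_with_index(self):
        frames = np.zeros((2, 10, 10), np.uint8)
        frames[0, 3:6, 3:6] = 1
        with pytest.raises(ValueError, match="frame 1"):
            area_curve(as_masks(frames))


class TestPartitionQuadrants:
    def test_partition_covers_mask_disjointly(self, disk_mask):
        part = partition_quadrants(disk_mask)
        inside = part.sector_map >= 0
        assert np.array_equal(inside, disk_mask)
        union = np.zeros_like(disk_mask)
        for lab in part.labels:
            q = part.mask_for(lab)
            assert not (union & q).any()
            union |= q
        assert np.array_equal(union, disk_mask)

    def test_centered_disk_quadrants_near_equal(self, disk_mask):
        """Each 90-degree sector of a disk holds ~1/4 of the area (pixel oracle)."""
        part = partition_quadrants(disk_mask)
        total = disk_mask.sum()
        for lab in part.labels:
            assert part.mask_for(lab).sum() == pytest.approx(total / 4, rel=0.02)

    def test_rotation_by_90_shifts_labels_cyclically(self, disk_mask):
        p60 = partition_quadrants(disk_mask, rotation_deg=60)
        p150 = partition_quadrants(disk_mask, rotation_deg=150)
        # sector k at 150 deg covers the same pixels as sector k+1 at 60 deg
        for k in range(4):
            np.testing.assert_array_equal(
                p150.sector_map == k, p60.sector_map == (k + 1) % 4
            )


class TestCompliance:
    def test_hand_computed_value(self):
        # (1000 - 900) mm^2 over (120 - 80) mmHg = 2.5 mm^2/mmHg
        curve = AreaCurve(total=np.array([900.0, 1000.0]), per_quadrant={})
        assert global_compliance(curve, PressurePair(120, 80)) == pytest.approx(2.5)

    def test_constant_curve_zero(self):
        curve = AreaCurve(total=np.full(5, 800.0), per_quadrant={})
        assert global_compliance(curve, PressurePair(120, 80)) == 0.0

    def test_phantom_truth_recovery(self, default_phantom):
        cfg, _, masks, truth = default_phantom
        curve = area_curve(masks)
        rec = global_compliance(curve, cfg.pressure_pair)
        assert rec == pytest.approx(truth.true_compliance, rel=0.02)


class TestPerimeter:
    def test_circle_perimeter_oracle(self):
        m = make_disk(128, (63.5, 63.5), 20)
        curve = perimeter_curve(as_masks(m))
        assert curve.total[0] == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_quadrant_arcs_of_disk_near_equal(self):
        m = make_disk(128, (63.5, 63.5), 30)
        curve = perimeter_curve(as_masks(m))
        for lab in QUADRANT_ORDER:
            assert curve.per_quadrant[lab][0] == pytest.approx(curve.total[0] / 4, rel=0.02)

    def test_arcs_sum_to_perimeter(self, default_phantom):
        _, _, masks, _ = default_phantom
        curve = perimeter_curve(masks)
        arc_sum = sum(curve.per_quadrant.values())
        assert np.allclose(arc_sum, curve.total, rtol=0.005)

    def test_doubling_spacing_doubles_perimeters(self, disk_mask):
        c1 = perimeter_curve(as_masks(disk_mask, 1.0))
        c2 = perimeter_curve(as_masks(disk_mask, 2.0))
        assert c2.total[0] == pytest.approx(2 * c1.total[0])
        for lab in QUADRANT_ORDER:
            assert c2.per_quadrant[lab][0] == pytest.approx(2 * c1.per_quadrant[lab][0])


class TestStrain:
    def test_hand_computed_value(self):
        curve = PerimeterCurve(total=np.array([100.0, 110.0]), per_quadrant={})
        assert global_strain(curve) == pytest.approx(0.1)

    def test_constant_curve_zero(self):
        curve = PerimeterCurve(total=np.full(4, 90.0), per_quadrant={})
        assert global_strain(curve) == 0.0

    def test_uniform_scaling_strain_recovered(self):
        masks = np.stack(
            [make_disk(192, (95.5, 95.5), 40.0), make_disk(192, (95.5, 95.5), 44.0)]
        )
        strain = global_strain(perimeter_curve(as_masks(masks)))
        assert strain == pytest.approx(0.1, rel=0.03)


class TestLocalProperties:
    def test_uniform_disk_local_compliance_quarter_of_global(self):
        masks = np.stack(
            [make_disk(192, (95.5, 95.5), 40.0), make_disk(192, (95.5, 95.5), 44.0)]
        )
        pp = PressurePair(120, 80)
        local = local_compliance(as_masks(masks), pp)
        total = global_compliance(area_curve(as_masks(masks)), pp)
        for v in local.values():
            assert v == pytest.approx(total / 4, rel=0.03)

    def test_static_masks_zero_everywhere(self, disk_mask):
        masks = as_masks(np.stack([disk_mask, disk_mask]))
        assert all(v == 0.0 for v in local_compliance(masks, PressurePair(120, 80)).values())
        assert all(v == 0.0 for v in local_strain(masks).values())

    def test_quadrant_sum_at_least_global(self, default_phantom):
        """Per-quadrant extrema are independent, so their sum >= the global swing."""
        cfg, _, masks, _ = default_phantom
        pp = cfg.pressure_pair
        local = local_compliance(masks, pp)
        total = global_compliance(area_curve(masks), pp)
        assert sum(local.values()) >= total - 1e-9

    def test_anisotropic_pulsation_strains_ordered(self):
        """A vessel pulsating along one axis strains most in that axis' sectors."""
        n = 192
        rr, cc = np.mgrid[0:n, 0:n].astype(float)
        frames = []
        for a in (40.0, 46.0):  # columns axis dilates, rows axis fixed
            frames.append(((cc - 95.5) / a) ** 2 + ((rr - 95.5) / 40.0) ** 2 <= 1.0)
        # rotation 0: sectors at 0-90-180-270; 'lateral'+'medial' contain the
        # column axis under the default counterclockwise label cycle
        strains = local_strain(as_masks(np.stack(frames)), rotation_deg=-45.0)
        assert strains["lateral"] > strains["anterior"]
        assert strains["medial"] > strains["posterior"]


class TestElasticityReport:
    def test_matches_truth_end_to_end(self, default_phantom):
        cfg, _, masks, truth = default_phantom
        rep = elasticity_report(masks, cfg.pressure_pair)
        assert rep.global_compliance == pytest.approx(truth.true_compliance, rel=0.02)
        assert rep.global_strain == pytest.approx(truth.true_strain, rel=0.02)
        assert rep.area_max >= rep.area_min
        assert rep.perimeter_max >= rep.perimeter_min

    def test_deterministic(self, small_phantom):
        cfg, _, masks, _ = small_phantom
        r1 = elasticity_report(masks, cfg.pressure_pair)
        r2 = elasticity_report(masks, cfg.pressure_pair)
        assert r1.to_json_dict() == r2.to_json_dict()

    def test_json_row_layout(self, small_phantom):
        cfg, _, masks, _ = small_phantom
        rep = elasticity_report(masks, cfg.pressure_pair)
        d = rep.to_json_dict()
        assert list(d["local_compliance_mm2_per_mmHg"]) == list(QUADRANT_ORDER)
        row = rep.to_row()
        assert row.shape[0] == 1
        assert "compliance_medial" in row.columns
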