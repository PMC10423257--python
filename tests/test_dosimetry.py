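"""Activity partitioning, LED dose conversion and partition-model planning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirtdosim import (ImageGrid, activity_for_normal_dose, build_activity_map,
                       decay_correct, led_dose_map, partition_model_plan,
                       simulate_acquisition, tumor_to_normal_ratio, voi_dose)


def grid_of(values, spacing=2.0):
    return ImageGrid(np.asarray(values, dtype=float), spacing, units="kBq/mL")


class TestDecayCorrect:
    def test_zero_interval_is_identity(self):
        assert decay_correct(1.5, 0.0) == 1.5

    def test_one_half_life_doubles(self):
        assert decay_correct(1.0, 64.05) == pytest.approx(2.0)

    def test_ten_hours(self):
        # 2**(10 / 64.05) = 1.1143
        assert decay_correct(1.0, 10.0) == pytest.approx(1.1143, abs=5e-5)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(1.0, -1.0)


class TestActivityMap:
    def test_uniform_image_partitions_evenly(self):
        am = build_activity_map(grid_of(np.full((5, 5, 4), 3.0)), 1.0)
        assert np.allclose(am.voxel_activity_GBq, 1.0 / 100)

    def test_total_activity_conserved(self, rng):
        img = grid_of(rng.random((9, 8, 7)))
        am = build_activity_map(img, 2.7)
        assert am.voxel_activity_GBq.sum() == pytest.approx(2.7, rel=1e-12)

    def test_scale_invariance_of_relative_intensity(self, rng):
        values = rng.random((6, 6, 6))
        am1 = build_activity_map(grid_of(values), 1.5)
        am2 = build_activity_map(grid_of(values * 10.0), 1.5)
        assert np.allclose(am1.voxel_activity_GBq, am2.voxel_activity_GBq)

    def test_spill_out_fraction(self):
        values = np.zeros((4, 4, 4))
        values[:2] = 1.0
        liver = np.zeros((4, 4, 4), bool)
        liver[0] = True  # half of the signal is outside
        am = build_activity_map(grid_of(values), 1.0, liver_mask=liver)
        assert am.out_of_liver_fraction == pytest.approx(0.5)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            build_activity_map(grid_of(np.zeros((3, 3, 3))), 1.0)


class TestLEDDose:
    def test_fifty_gray_per_gbq_per_kg(self):
        # 1 GBq uniformly in 1 kg of tissue -> mean dose 50 Gy
        img = grid_of(np.full((10, 10, 10), 1.0), spacing=10.0)  # 1 L total
        am = build_activity_map(img, 1.0)
        dm = led_dose_map(am, density_g_per_mL=1.0)  # 1 L * 1 g/mL = 1 kg
        rec = voi_dose(dm, np.ones(img.shape, bool))
        assert rec.mean_dose_Gy_uncorrected == pytest.approx(50.0, rel=1e-12)

    def test_direct_formula_single_voxel(self):
        # 1e-5 GBq in a 2 mm voxel (8.24e-6 kg at 1.03 g/mL) -> 60.68 Gy
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 1.0
        am = build_activity_map(grid_of(values, spacing=2.0), 1e-5)
        dm = led_dose_map(am, density_g_per_mL=1.03)
        assert dm.voxel_dose_Gy[1, 1, 1] == pytest.approx(60.68, abs=0.005)

    def test_zero_activity_zero_dose(self):
        values = np.zeros((3, 3, 3))
        values[0, 0, 0] = 5.0
        am = build_activity_map(grid_of(values), 1.0)
        am.voxel_activity_GBq[:] = 0.0
        assert np.all(led_dose_map(am).voxel_dose_Gy == 0.0)

    def test_dose_linear_in_administered_activity(self, rng):
        img = grid_of(rng.random((6, 6, 6)))
        d1 = led_dose_map(build_activity_map(img, 1.0)).voxel_dose_Gy
        d2 = led_dose_map(build_activity_map(img, 2.0)).voxel_dose_Gy
        assert np.allclose(d2, 2.0 * d1)

    def test_invalid_density_rejected(self, rng):
        am = build_activity_map(grid_of(rng.random((3, 3, 3))), 1.0)
        with pytest.raises(ValueError):
            led_dose_map(am, density_g_per_mL=0.0)


class TestVOIDose:
    def test_uniform_map_mean(self):
        img = grid_of(np.ones((4, 4, 4)))
        dm = led_dose_map(build_activity_map(img, 1.0))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        rec = voi_dose(dm, mask)
        assert rec.mean_dose_Gy_uncorrected == pytest.approx(dm.voxel_dose_Gy[0, 0, 0])
        assert rec.volume_mL == pytest.approx(8 * dm.voxel_volume_mL)
        assert rec.mass_kg == pytest.approx(rec.volume_mL * 1.03 / 1000.0)

    def test_single_voxel_mask(self, rng):
        img = grid_of(rng.random((4, 4, 4)) + 0.1)
        dm = led_dose_map(build_activity_map(img, 1.0))
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 1, 3] = True
        assert voi_dose(dm, mask).mean_dose_Gy_uncorrected == dm.voxel_dose_Gy[2, 1, 3]

    def test_brute_force_mean_oracle(self, rng):
        img = grid_of(rng.random((8, 8, 8)) + 0.01)
        dm = led_dose_map(build_activity_map(img, 1.0))
        mask = rng.random((8, 8, 8)) > 0.6
        total, n = 0.0, 0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    if mask[i, j, k]:
                        total += dm.voxel_dose_Gy[i, j, k]
                        n += 1
        assert voi_dose(dm, mask).mean_dose_Gy_uncorrected == pytest.approx(
            total / n, rel=1e-12)

    def test_empty_mask_rejected(self, rng):
        dm = led_dose_map(build_activity_map(grid_of(rng.random((3, 3, 3))), 1.0))
        with pytest.raises(ValueError, match="empty"):
            voi_dose(dm, np.zeros((3, 3, 3), bool))


class TestTumorToNormalRatio:
    def test_uniform_map_gives_unity(self):
        am = build_activity_map(grid_of(np.ones((6, 6, 6))), 1.0)
        t = np.zeros((6, 6, 6), bool)
        t[:2] = True
        assert tumor_to_normal_ratio(am, t, ~t) == pytest.approx(1.0)

    def test_blur_reduces_measured_ratio(self, two_lesion_patient):
        spec, (maa, _, vois, _) = two_lesion_patient
        tumor, normal = vois.label_map >= 2, vois.mask(1)
        am_truth = build_activity_map(maa, 1.5)
        blurred = simulate_acquisition(maa, fwhm_mm=10.0)
        am_blur = build_activity_map(blurred, 1.5)
        true_ratio = tumor_to_normal_ratio(am_truth, tumor, normal)
        assert true_ratio == pytest.approx(spec.tn_ratio, rel=1e-12)
        assert tumor_to_normal_ratio(am_blur, tumor, normal) < true_ratio

    def test_overlapping_masks_rejected(self):
        am = build_activity_map(grid_of(np.ones((3, 3, 3))), 1.0)
        mask = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="overlap"):
            tumor_to_normal_ratio(am, mask, mask)


class TestPartitionModel:
    def test_symmetric_split(self):
        plan = partition_model_plan(1.0, tn_ratio=1.0, tumor_mass_kg=0.5,
                                    normal_mass_kg=0.5)
        assert plan.tumor_dose_Gy == pytest.approx(plan.normal_dose_Gy)

    def test_closed_form_example(self):
        # A=1.5 GBq, r=3.8, m_T=0.1 kg, m_N=1.0 kg
        plan = partition_model_plan(1.5, 3.8, 0.1, 1.0)
        assert plan.tumor_dose_Gy == pytest.approx(206.5, abs=0.05)
        assert plan.normal_dose_Gy == pytest.approx(54.3, abs=0.05)
        assert plan.tumor_activity_GBq + plan.normal_activity_GBq == \
            pytest.approx(1.5)

    def test_plan_then_invert_round_trip(self):
        plan = partition_model_plan(2.3, 4.1, 0.2, 1.3, shunt_fraction=0.05)
        recovered = activity_for_normal_dose(plan.normal_dose_Gy, 4.1, 0.2, 1.3,
                                             shunt_fraction=0.05)
        assert recovered == pytest.approx(2.3, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=st.floats(0.1, 10.0), r=st.floats(0.1, 20.0),
           mt=st.floats(0.01, 2.0), mn=st.floats(0.1, 2.5),
           s=st.floats(0.0, 0.5))
    def test_dose_ratio_equals_uptake_ratio(self, a, r, mt, mn, s):
        plan = partition_model_plan(a, r, mt, mn, shunt_fraction=s)
        assert plan.tumor_dose_Gy / plan.normal_dose_Gy == pytest.approx(r)
        assert plan.tumor_activity_GBq + plan.normal_activity_GBq == \
            pytest.approx(a * (1.0 - s))

    def test_degenerate_masses_rejected(self):
        with pytest.raises(ValueError):
            partition_model_plan(1.0, 3.8, 0.0, 1.0)
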