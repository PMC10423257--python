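"""Phantom/patient generators and the acquisition simulator."""

import numpy as np
import pytest

from sirtdosim import (ImageGrid, Lesion, PatientSpec, PhantomSpec, VOISet,
                       make_nema_phantom, make_synthetic_patient,
                       simulate_acquisition)


def single_sphere_spec(diameter_mm, spacing=2.0, conc=40.0, bg=0.0):
    size = diameter_mm + 40.0
    return PhantomSpec(sphere_diameters_mm=(diameter_mm,),
                       sphere_conc_kBq_mL=conc, background_conc_kBq_mL=bg,
                       body_dimensions_mm=(size, size, size),
                       grid_spacing_mm=spacing, ring_radius_mm=0.0)


class TestPhantom:
    def test_equal_concentrations_give_uniform_body(self):
        spec = PhantomSpec(sphere_conc_kBq_mL=7.0, background_conc_kBq_mL=7.0)
        truth, vois = make_nema_phantom(spec)
        body = vois.label_map > 0
        assert np.allclose(truth.values[body], 7.0)
        assert np.all(truth.values[~body] == 0.0)

    @pytest.mark.parametrize("diameter", [10.0, 17.0, 28.0, 37.0])
    def test_sphere_activity_matches_analytic_volume(self, diameter):
        # on a cold background the whole grid activity is the sphere's:
        # conc * (pi/6) d^3, the analytic oracle
        spec = single_sphere_spec(diameter)
        truth, _ = make_nema_phantom(spec)
        total_kBq = truth.values.sum() * truth.voxel_volume_mL
        analytic = spec.sphere_conc_kBq_mL * np.pi / 6 * diameter ** 3 / 1000.0
        assert total_kBq == pytest.approx(analytic, rel=5e-3)

    def test_mask_volume_converges_to_analytic(self):
        diameter = 22.0
        analytic = np.pi / 6 * diameter ** 3 / 1000.0
        errors = []
        for spacing in (4.0, 2.0, 1.0):
            _, vois = make_nema_phantom(single_sphere_spec(diameter, spacing))
            (lid,) = vois.ids_by_role("sphere_insert")
            errors.append(abs(vois.volume_mL(lid) - analytic) / analytic)
        assert errors[2] < errors[0]
        assert errors[2] < 0.01

    def test_overlapping_spheres_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_nema_phantom(PhantomSpec(ring_radius_mm=5.0))

    def test_sphere_outside_body_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_nema_phantom(PhantomSpec(body_dimensions_mm=(100.0, 100.0, 60.0)))

    def test_decreasing_diameters_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PhantomSpec(sphere_diameters_mm=(13.0, 10.0))


class TestAcquisition:
    def test_zero_blur_is_identity(self, default_phantom):
        _, truth, _ = default_phantom
        acq = simulate_acquisition(truth, fwhm_mm=0.0)
        assert np.array_equal(acq.values, truth.values)
        assert acq.modality == "spect_like"

    def test_signal_conserved_away_from_edges(self, padded_phantom):
        _, truth, _ = padded_phantom
        acq = simulate_acquisition(truth, fwhm_mm=10.0, motion_amp_mm=15.0)
        assert acq.values.sum() == pytest.approx(truth.values.sum(), rel=0.01)

    def test_small_sphere_loses_more_peak_signal(self, default_phantom):
        # convolution property: at equal true concentration the 10 mm sphere's
        # maximum falls below the 37 mm sphere's after a 10 mm FWHM blur
        _, truth, vois = default_phantom
        acq = simulate_acquisition(truth, fwhm_mm=10.0)
        by_diam = {vois.labels[lid].diameter_mm: lid
                   for lid in vois.ids_by_role("sphere_insert")}
        peak_small = acq.values[vois.mask(by_diam[10.0])].max()
        peak_large = acq.values[vois.mask(by_diam[37.0])].max()
        assert peak_small < peak_large

    def test_noise_is_seed_deterministic(self, default_phantom):
        _, truth, _ = default_phantom
        a = simulate_acquisition(truth, 10.0, noise_scale=2.0, seed=5)
        b = simulate_acquisition(truth, 10.0, noise_scale=2.0, seed=5)
        c = simulate_acquisition(truth, 10.0, noise_scale=2.0, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize("kwargs", [
        {"fwhm_mm": -1.0}, {"fwhm_mm": 5.0, "motion_amp_mm": -2.0},
        {"fwhm_mm": 5.0, "noise_scale": 0.0}])
    def test_invalid_parameters_rejected(self, default_phantom, kwargs):
        _, truth, _ = default_phantom
        with pytest.raises(ValueError):
            simulate_acquisition(truth, **kwargs)


class TestPatient:
    def test_zero_discrepancy_gives_identical_grids(self):
        spec = PatientSpec(lesions=[Lesion((10.0, 0.0, 0.0), 20.0)],
                           discrepancy_sigma=0.0, seed=1)
        maa, y90, _, _ = make_synthetic_patient(spec)
        assert np.array_equal(maa.values, y90.values)

    def test_truth_uptake_ratio_is_exact(self, two_lesion_patient):
        spec, (maa, _, vois, _) = two_lesion_patient
        lesion = vois.label_map >= 2
        normal = vois.mask(1)
        ratio = maa.values[lesion].mean() / maa.values[normal].mean()
        assert ratio == pytest.approx(spec.tn_ratio, rel=1e-12)

    def test_fixed_seed_reproduces_bitwise(self, two_lesion_patient):
        spec, (maa, y90, vois, table) = two_lesion_patient
        maa2, y902, vois2, table2 = make_synthetic_patient(spec)
        assert np.array_equal(maa.values, maa2.values)
        assert np.array_equal(y90.values, y902.values)
        assert np.array_equal(vois.label_map, vois2.label_map)
        assert table.equals(table2)

    def test_lesion_outside_liver_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            PatientSpec(lesions=[Lesion((65.0, 0.0, 0.0), 20.0)])

    def test_overlapping_lesions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PatientSpec(lesions=[Lesion((0.0, 0.0, 0.0), 20.0),
                                 Lesion((5.0, 0.0, 0.0), 20.0)])

    def test_truth_table_matches_label_volumes(self, two_lesion_patient):
        _, (_, _, vois, table) = two_lesion_patient
        for _, row in table.iterrows():
            assert row["volume_mL"] == pytest.approx(
                vois.volume_mL(int(row["lesion_id"])))


class TestNiftiRoundTrip:
    def test_image_grid(self, tmp_path, rng):
        grid = ImageGrid(rng.random((6, 5, 4)), (2.0, 3.0, 4.0),
                         origin_mm=(-6.0, -7.5, -8.0), units="kBq/mL")
        path = grid.to_nifti(tmp_path / "g.nii.gz")
        back = ImageGrid.from_nifti(path, units="kBq/mL")
        assert np.allclose(back.values, grid.values)
        assert np.allclose(back.spacing_mm, grid.spacing_mm)
        assert np.allclose(back.origin_mm, grid.origin_mm)

    def test_voi_set_with_sidecar(self, tmp_path, two_lesion_patient):
        _, (_, _, vois, _) = two_lesion_patient
        path = vois.to_nifti(tmp_path / "labels.nii.gz")
        back = VOISet.from_nifti(path)
        assert np.array_equal(back.label_map, vois.label_map)
        assert back.labels[2].role == "lesion"
        assert back.labels[2].diameter_mm == vois.labels[2].diameter_mm
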