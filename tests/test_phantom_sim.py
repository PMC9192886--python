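"""Simulator checks: phantom geometry against analytic volumes, Poisson count
statistics against the scan-time ratio, and determinism contracts."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from spectboost.exceptions import ContractError, GeometryError, PlacementError
from spectboost.phantom_sim import (AcquisitionSpec, PhantomSpec, blur_activity,
                                    build_phantom, expected_counts,
                                    generate_synthetic_subject,
                                    make_paired_dataset, simulate_acquisition)
from spectboost.volume import Volume


class TestPhantomSpec:
    def test_default_cylinder_volume_roundtrip(self):
        spec = PhantomSpec()
        r, h = spec.cylinder_radius_mm, spec.interior_length_mm
        assert np.pi * r ** 2 * h / 1000.0 == pytest.approx(9700, rel=1e-9)

    def test_decreasing_diameters_rejected(self):
        with pytest.raises(ContractError):
            PhantomSpec(sphere_diameters_mm=(10, 9, 17, 22, 28, 37))

    def test_ring_must_clear_axis(self):
        with pytest.raises(ContractError):
            PhantomSpec(ring_radius_mm=15.0)


@pytest.fixture(scope="module")
def default_phantom():
    return build_phantom(PhantomSpec()), PhantomSpec()


class TestBuildPhantom:
    def test_six_connected_spheres(self, default_phantom):
        (_, mask, _), _ = default_phantom
        _, n = ndimage.label(mask.data)
        assert n == 6

    def test_largest_sphere_volume_matches_analytic(self, default_phantom):
        (_, mask, _), spec = default_phantom
        labels, _ = ndimage.label(mask.data)
        sizes = np.bincount(labels.ravel())[1:]
        vox_vol = spec.voxel_size_mm ** 3
        analytic = 4 / 3 * np.pi * 18.5 ** 3  # 26 522 mm^3
        assert sizes.max() * vox_vol == pytest.approx(analytic, rel=0.05)

    def test_voxelized_cylinder_volume_within_two_percent(self, default_phantom):
        (activity, _, _), spec = default_phantom
        fill_vol_ml = (activity.data > 0).sum() * spec.voxel_size_mm ** 3 / 1000.0
        assert fill_vol_ml == pytest.approx(spec.cylinder_volume_ml, rel=0.02)

    def test_activity_levels(self, default_phantom):
        (activity, mask, ct), spec = default_phantom
        m = mask.data.astype(bool)
        assert set(np.unique(activity.data)) == {0.0, 1.0, spec.activity_ratio}
        assert np.all(activity.data[m] == spec.activity_ratio)
        assert len(np.unique(ct.data)) == 3  # air / water / shell

    def test_ratio_one_degenerates_to_uniform(self):
        spec = PhantomSpec(grid_shape=(32, 64, 64), voxel_size_mm=6.0, activity_ratio=1.0)
        activity, mask, _ = build_phantom(spec)
        inside = activity.data > 0
        assert np.all(activity.data[inside] == 1.0)

    def test_sphere_centres_on_ring_and_plane(self):
        spec = PhantomSpec()
        for cz, cy, cx in spec.sphere_centers_mm():
            assert cz == spec.sphere_plane_depth_mm
            assert np.hypot(cy, cx) == pytest.approx(spec.ring_radius_mm)

    def test_too_small_grid_names_dimension(self):
        with pytest.raises(GeometryError, match="slice"):
            build_phantom(PhantomSpec(grid_shape=(16, 256, 256), voxel_size_mm=1.95))
        with pytest.raises(GeometryError, match="row|col"):
            build_phantom(PhantomSpec(grid_shape=(200, 64, 64), voxel_size_mm=1.95))


class TestSimulateAcquisition:
    def test_zero_activity_zero_background_gives_zero_counts(self):
        act = Volume(np.zeros((8, 8, 8)), 2.0, "activity")
        counts = simulate_acquisition(act, AcquisitionSpec(background_counts_rate=0.0))
        assert counts.data.sum() == 0
        assert counts.modality == "spect_counts"

    def test_count_ratio_matches_dwell_ratio(self):
        """Expected fast/standard count ratio is 3/20 = 0.15 (to 1%)."""
        act = Volume(np.full((50, 50, 50), 4.0), 2.0, "activity")  # 125k voxels
        acq = dict(n_projections=60, psf_fwhm_mm=0.0,
                   sensitivity_counts_per_kBq_s=1.0, background_counts_rate=0.0)
        fast = simulate_acquisition(act, AcquisitionSpec(3.0, rng_seed=1, **acq))
        std = simulate_acquisition(act, AcquisitionSpec(20.0, rng_seed=2, **acq))
        assert std.data.mean() >= 100
        ratio = fast.data.mean() / std.data.mean()
        assert ratio == pytest.approx(3 / 20, rel=0.01)

    def test_same_seed_bit_identical(self):
        act = Volume(np.full((16, 16, 16), 2.0), 1.95, "activity")
        acq = AcquisitionSpec(rng_seed=99)
        a = simulate_acquisition(act, acq)
        b = simulate_acquisition(act, acq)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_activity_rejected(self):
        act = Volume(np.full((4, 4, 4), 1.0), 1.0, "activity")
        act.data[0, 0, 0] = -1
        with pytest.raises(ContractError):
            simulate_acquisition(act, AcquisitionSpec())

    def test_count_conservation_in_expectation(self):
        """Total simulated counts match total expected counts within 3 sigma."""
        act = Volume(np.full((40, 40, 40), 3.0), 2.0, "activity")
        acq = AcquisitionSpec(20.0, psf_fwhm_mm=5.0, rng_seed=3)
        lam = expected_counts(act, acq).data
        counts = simulate_acquisition(act, acq).data
        total, expect = counts.sum(), lam.sum()
        assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_blur_preserves_total_activity(self):
        rng = np.random.default_rng(0)
        act = Volume(np.pad(rng.random((20, 20, 20)), 10), 2.0, "activity")
        blurred = blur_activity(act, 8.0)
        assert blurred.data.sum() == pytest.approx(act.data.sum(), rel=1e-6)

    def test_expected_counts_linear_in_dwell(self):
        act = Volume(np.full((10, 10, 10), 2.0), 2.0, "activity")
        dwells = [3.0, 10.0, 20.0]
        totals = [expected_counts(act, AcquisitionSpec(d, psf_fwhm_mm=0.0)).data.sum()
                  for d in dwells]
        slopes = [t / d for t, d in zip(totals, dwells)]
        assert max(slopes) == pytest.approx(min(slopes), rel=1e-9)


class TestSyntheticSubject:
    def test_zero_lesions_empty_mask(self):
        _, mask, _ = generate_synthetic_subject(0, 0, (16, 64, 64), 6.0)
        assert mask.data.sum() == 0

    def test_three_lesions_three_components(self):
        _, mask, _ = generate_synthetic_subject(3, 3, (32, 64, 64), 6.0)
        _, n = ndimage.label(mask.data)
        assert n == 3

    def test_same_seed_identical_triplet(self):
        a = generate_synthetic_subject(7, 2, (16, 64, 64), 6.0)
        b = generate_synthetic_subject(7, 2, (16, 64, 64), 6.0)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_ct_shares_structure(self):
        activity, mask, ct = generate_synthetic_subject(1, 1, (16, 64, 64), 6.0)
        bone_ct = ct.data == 700.0
        assert bone_ct.any()
        assert np.all(activity.data[bone_ct] > 1.0)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_synthetic_subject(0, 50, (8, 32, 32), 6.0, max_retries=5)


class TestPairedDataset:
    def test_phantom_only_composition(self, fast_acq, std_acq, desk_phantom_spec):
        cases = make_paired_dataset(fast_acq, std_acq, seed=1,
                                    phantom_spec=desk_phantom_spec)
        assert len(cases) == 1
        _, mask, _ = build_phantom(desk_phantom_spec)
        np.testing.assert_array_equal(cases[0].mask.data, mask.data)

    def test_shapes_consistent_across_subjects(self, fast_acq, std_acq):
        cases = make_paired_dataset(fast_acq, std_acq, seed=2, n_subjects=3,
                                    subject_grid_shape=(8, 32, 32), subject_voxel_mm=8.0)
        assert len(cases) == 3
        shapes = {v.shape for c in cases for v in (c.fast, c.ct, c.standard, c.mask)}
        assert shapes == {(8, 32, 32)}

    def test_fast_standard_noise_residuals_uncorrelated(self, desk_phantom_spec):
        acq = dict(n_projections=60, psf_fwhm_mm=0.0, background_counts_rate=0.0)
        fast_acq = AcquisitionSpec(3.0, **acq)
        std_acq = AcquisitionSpec(20.0, **acq)
        spec = PhantomSpec(grid_shape=(60, 80, 80), voxel_size_mm=4.0)
        case = make_paired_dataset(fast_acq, std_acq, seed=3, phantom_spec=spec,
                                   keep_activity=True)[0]
        lam_f = expected_counts(case.activity, fast_acq).data
        lam_s = expected_counts(case.activity, std_acq).data
        sel = lam_s > 0
        assert sel.sum() >= 1e5
        rf = (case.fast.data - lam_f)[sel]
        rs = (case.standard.data - lam_s)[sel]
        r = np.corrcoef(rf, rs)[0, 1]
        assert abs(r) < 0.02

    def test_mismatched_physics_rejected(self, fast_acq):
        other = replace(fast_acq, seconds_per_projection=20.0, psf_fwhm_mm=2.0)
        with pytest.raises(ContractError):
            make_paired_dataset(fast_acq, other, seed=0, n_subjects=1)
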