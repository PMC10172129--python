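"""Map assembly, registration, projections, ROI statistics, bead PSF."""

import numpy as np
import pytest

from lsbm.errors import InvalidParameterError, RangeError
from lsbm.mapping import (
    ROITimeSeries,
    RegistrationTransform,
    ShiftVolume,
    assemble_volume,
    bead_psf_fwhm,
    register_overlay,
    relative_timeseries,
    rescale_to_fluorescence,
    reslice_and_median_project,
    roi_quantify,
)
from lsbm.reconstruction import BrillouinMeasurement


def make_measurement(shift=5.05, valid=True, row=None):
    return BrillouinMeasurement(
        shift=shift, linewidth=0.4, amplitude=100.0, snr_db=30.0,
        stokes_fit=None, antistokes_fit=None, goodness_r2=0.99,
        residual_rms=1.0, n_iterations=10, valid=valid, row=row,
    )


class TestAssembleVolume:
    def test_bookkeeping_shapes_and_voxels(self):
        lines = [[make_measurement() for _ in range(264)] for _ in range(10)]
        vol = assemble_volume(lines, 1.5 * np.arange(10),
                              spatial_sampling_um=0.7)
        assert vol.shift.shape == (264, 10)
        assert vol.voxel_size_um[0] == pytest.approx(0.7)
        assert vol.voxel_size_um[1] == pytest.approx(1.5)

    def test_single_line_volume(self):
        vol = assemble_volume([[make_measurement()] * 8], [0.0])
        assert vol.shift.shape == (8, 1)

    def test_shuffled_positions_sorted(self):
        rng = np.random.default_rng(0)
        shifts = rng.uniform(5.0, 5.1, 6)
        lines = [[make_measurement(s)] for s in shifts]
        pos = np.array([3.0, 0.0, 4.5, 1.5, 7.5, 6.0])
        vol = assemble_volume(lines, pos)
        order = np.argsort(pos)
        assert np.allclose(vol.shift[0], shifts[order])

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(InvalidParameterError):
            assemble_volume([[make_measurement()] * 3,
                             [make_measurement()] * 4], [0.0, 1.5])


class TestRescale:
    def test_output_dimensions_floor(self):
        arr = np.random.default_rng(1).uniform(5.0, 5.1, (100, 40))
        out, _ = rescale_to_fluorescence(arr, RegistrationTransform())
        assert out.shape == (251, 100)  # floor(100*2.5138), floor(40*2.5138)

    def test_unit_scale_is_identity(self):
        arr = np.random.default_rng(2).uniform(0, 1, (20, 30))
        out, _ = rescale_to_fluorescence(arr, RegistrationTransform(xy_scale=1.0))
        assert np.array_equal(out, arr)

    def test_constant_map_preserved(self):
        arr = np.full((37, 21), 5.05)
        out, _ = rescale_to_fluorescence(arr, RegistrationTransform())
        assert np.allclose(out, 5.05)

    def test_validity_mask_stays_boolean(self):
        arr = np.full((10, 10), 5.0)
        valid = np.zeros((10, 10), bool)
        valid[3:7, 3:7] = True
        _, out_valid = rescale_to_fluorescence(arr, RegistrationTransform(),
                                               valid=valid)
        assert out_valid.dtype == bool
        assert 0 < out_valid.sum() < out_valid.size

    def test_inverse_rescale_recovers_constant(self):
        arr = np.full((40, 40), 5.05)
        up, _ = rescale_to_fluorescence(arr, RegistrationTransform(xy_scale=2.5))
        down, _ = rescale_to_fluorescence(up, RegistrationTransform(xy_scale=0.4))
        assert np.allclose(down, 5.05)


class TestRegisterOverlay:
    def test_zero_offset_equal_sizes_identity(self):
        fluo = np.random.default_rng(3).uniform(0, 1, (60, 60))
        bri = np.random.default_rng(4).uniform(5, 5.1, (60, 60))
        out_f, out_b = register_overlay(
            fluo, bri, RegistrationTransform(y_offset=30, x_offset=0))
        assert np.array_equal(out_f, fluo)
        assert np.array_equal(out_b, bri)

    def test_known_shift_recovered_by_true_offset(self):
        # phantom pair with a 12-px x displacement: applying the true offset
        # aligns the mask centroids to within a pixel
        fluo = np.zeros((100, 80))
        fluo[40:50, 30:40] = 1.0
        bri = np.zeros((60, 80))
        bri[28:38, 30:40] = 1.0  # same feature, x shifted by 40-28=12
        out_f, out_b = register_overlay(
            fluo, bri, RegistrationTransform(y_offset=40, x_offset=12))

        def centroid(img):
            idx = np.argwhere(img > 0.5)
            return idx.mean(axis=0)

        assert np.all(np.abs(centroid(out_f) - centroid(out_b)) <= 1.0)

    def test_y_offset_450_centers_900px_frame(self):
        fluo = np.zeros((20, 900))
        bri = np.zeros((20, 300))
        out_f, _ = register_overlay(fluo, bri,
                                    RegistrationTransform(y_offset=450))
        assert out_f.shape == (20, 300)
        # crop starts at 450 - 150 = 300: centered in the 900-px frame

    def test_offsets_outside_frame_rejected(self):
        with pytest.raises(RangeError):
            register_overlay(np.zeros((10, 10)), np.zeros((10, 10)),
                             RegistrationTransform(y_offset=450))


class TestMedianProjection:
    def test_identical_slices_project_to_themselves(self):
        vol = np.stack([np.full((4, 4), 5.05)] * 3, axis=2)
        out = reslice_and_median_project(vol, axis=2, slabs=[(0, 1, 2)])
        assert np.allclose(out[0], 5.05)

    def test_median_of_three_values(self):
        vol = np.zeros((1, 1, 3))
        vol[0, 0] = [5.00, 5.10, 5.02]
        out = reslice_and_median_project(vol, axis=2, slabs=[(0, 1, 2)])
        assert out[0][0, 0] == pytest.approx(5.02)

    def test_invalid_voxel_excluded(self):
        vol = np.zeros((1, 1, 3))
        vol[0, 0] = [5.00, np.nan, 5.10]
        out = reslice_and_median_project(vol, axis=2, slabs=[(0, 1, 2)])
        assert out[0][0, 0] == pytest.approx(5.05)  # mean of remaining pair

    def test_fully_invalid_slab_gives_nan(self):
        vol = np.full((2, 2, 2), np.nan)
        out = reslice_and_median_project(vol, axis=2, slabs=[(0, 1)])
        assert np.all(np.isnan(out[0]))

    def test_out_of_range_slab_rejected(self):
        with pytest.raises(RangeError):
            reslice_and_median_project(np.zeros((2, 2, 2)), 2, [(0, 5)])

    def test_permutation_invariance_within_slab(self):
        rng = np.random.default_rng(6)
        vol = rng.uniform(5.0, 5.2, (3, 3, 4))
        a = reslice_and_median_project(vol, 2, [(0, 1, 2, 3)])[0]
        b = reslice_and_median_project(vol[:, :, ::-1], 2, [(0, 1, 2, 3)])[0]
        assert np.allclose(a, b)


class TestROIQuantify:
    def test_uniform_region_mean_sd(self):
        arr = np.full((10, 10), 5.05)
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        out = roi_quantify(arr, mask, "mean")
        assert out["central"] == pytest.approx(5.05)
        assert out["dispersion"] == pytest.approx(0.0, abs=1e-12)
        assert out["n"] == 36

    def test_elevated_domain_recovered(self):
        rng = np.random.default_rng(8)
        arr = 5.05 + rng.normal(0, 0.004, (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        arr2 = arr + 0.015 * mask
        delta = (roi_quantify(arr2, mask)["central"]
                 - roi_quantify(arr, mask)["central"])
        assert delta == pytest.approx(0.015, abs=1e-9)

    def test_median_iqr_order_statistics(self):
        arr = np.array([[5.00, 5.01, 5.02, 5.03, 5.04]])
        mask = np.ones_like(arr, bool)
        out = roi_quantify(arr, mask, "median")
        assert out["central"] == pytest.approx(5.02)
        assert out["dispersion"][0] == pytest.approx(5.01)  # q25, linear interp
        assert out["dispersion"][1] == pytest.approx(5.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            roi_quantify(np.zeros((3, 3)), np.zeros((3, 3), bool))

    def test_mask_permutation_invariance(self):
        rng = np.random.default_rng(9)
        arr = rng.uniform(5.0, 5.2, (6, 6))
        mask = rng.uniform(size=(6, 6)) > 0.5
        base = roi_quantify(arr, mask)
        perm = np.random.default_rng(10).permutation(arr[mask])
        arr2 = arr.copy()
        arr2[mask] = perm
        assert roi_quantify(arr2, mask)["central"] == pytest.approx(base["central"])


class TestRelativeTimeseries:
    @staticmethod
    def _series(values):
        values = np.asarray(values, float)
        return ROITimeSeries(
            timepoints_min=np.arange(values.size, dtype=float),
            central=values,
            dispersion=np.full(values.size, 0.005),
            n_voxels=np.full(values.size, 100),
        )

    def test_reference_timepoint_becomes_zero(self):
        rel = relative_timeseries(self._series([5.05, 5.06, 5.065]), 0)
        assert rel.central[0] == 0.0
        assert rel.central[2] == pytest.approx(0.015)

    def test_constant_series_all_zero(self):
        rel = relative_timeseries(self._series([5.05] * 4), 0)
        assert np.allclose(rel.central, 0.0)

    def test_dispersion_untouched(self):
        rel = relative_timeseries(self._series([5.05, 5.07]), 0)
        assert np.allclose(rel.dispersion, 0.005)


class TestBeadPSF:
    def test_gaussian_fwhm_recovered(self):
        x = np.arange(-3.0, 3.0001, 0.1)
        sigma = 1.5 / (2 * np.sqrt(2 * np.log(2)))
        y = 1000.0 * np.exp(-0.5 * (x / sigma) ** 2) + 5.0
        assert bead_psf_fwhm(x, y) == pytest.approx(1.5, abs=0.05)

    def test_fwhm_sigma_ratio_constant(self):
        from lsbm.spectral_model import GAUSSIAN_FWHM_PER_SIGMA

        assert GAUSSIAN_FWHM_PER_SIGMA == pytest.approx(2.35482, abs=1e-5)

    def test_flat_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            bead_psf_fwhm(np.arange(10.0), np.ones(10))

    def test_monotone_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            bead_psf_fwhm(np.arange(10.0), np.arange(10.0))


class TestShiftVolume:
    def test_congruence_enforced(self):
        with pytest.raises(InvalidParameterError):
            ShiftVolume(
                shift=np.zeros((3, 3)), linewidth=np.zeros((3, 3)),
                snr=np.zeros((3, 3)), valid=np.ones((2, 2), bool),
            )

    def test_masked_shift_hides_invalid(self):
        valid = np.array([[True, False]])
        vol = ShiftVolume(
            shift=np.array([[5.0, 9.9]]), linewidth=np.zeros((1, 2)),
            snr=np.zeros((1, 2)), valid=valid,
        )
        out = vol.masked_shift()
        assert out[0, 0] == 5.0 and np.isnan(out[0, 1])
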