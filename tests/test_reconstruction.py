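"""Remap -> sum -> fit pipeline and characterization metrics."""

import math

import numpy as np
import pytest

from lsbm.calibration import CalibrationModel
from lsbm.errors import InvalidParameterError
from lsbm.reconstruction import (
    FitConfig,
    LinearSpectrum,
    compute_shift,
    compute_snr,
    fit_peak,
    fit_spectrum,
    measure_precision,
    measure_spectral_resolution,
    process_frame,
    process_row,
    remap_to_linear,
    sum_orders,
    target_grid,
)
from lsbm.simulator import WATER, simulate_frame, simulate_row_spectrum
from lsbm.spectral_model import (
    InstrumentKernel,
    SpectrometerConfig,
    lorentzian_profile,
    voigt_peak,
)


def doublet_spectrum(shift=5.05, fwhm=0.4, amp=1000.0, sigma=0.0, df=0.25,
                     fsr=15.15, noise_sd=0.0, seed=0):
    """Synthetic Stokes/anti-Stokes doublet directly on the linear grid."""
    grid = target_grid(fsr, df)
    if sigma > 0:
        y = voigt_peak(grid, amp, -shift, fwhm, sigma) + voigt_peak(
            grid, amp, shift, fwhm, sigma)
    else:
        y = lorentzian_profile(grid, amp, -shift, fwhm) + lorentzian_profile(
            grid, amp, shift, fwhm)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
    return LinearSpectrum(freq_ghz=grid, intensity=y, n_orders_summed=3)


class TestRemap:
    def test_passthrough_when_grids_coincide(self):
        # integer anchors + c1 = 1/target_df: every target sample coincides
        # with a source pixel and must pass through unchanged
        calib = CalibrationModel(
            order_anchors_px=np.array([40.0, 100.0, 160.0]),
            fsr=15.0, c1_px_per_ghz=4.0,
        )
        rng = np.random.default_rng(5)
        row = rng.uniform(10.0, 100.0, 220)
        specs = remap_to_linear(row, calib, target_df=0.25)
        for k, spec in enumerate(specs):
            idx = np.rint(calib.order_anchors_px[k]
                          + 4.0 * spec.freq_ghz).astype(int)
            inside = np.isfinite(spec.intensity)
            assert np.allclose(spec.intensity[inside], row[idx[inside]],
                               rtol=0, atol=1e-9)

    def test_constant_spectrum_stays_constant(self, calib):
        row = np.full(138, 42.0)
        specs = remap_to_linear(row, calib, 0.1)
        for spec in specs:
            inside = np.isfinite(spec.intensity)
            assert np.allclose(spec.intensity[inside], 42.0, atol=1e-9)

    def test_center_preserved_through_nonlinear_dispersion(self):
        # quadratic pixel law: remapped+fitted center within 1 MHz of truth
        from lsbm import rb_d2
        from lsbm.calibration import calibrate_frame
        from lsbm.simulator import simulate_calibration_frame

        cfg = SpectrometerConfig(dispersion_nonlinearity=0.03)
        frame = simulate_calibration_frame(
            cfg, rb_d2.EXTENDED_REFERENCE_LINES_GHZ)
        truth = frame.metadata["truth"]
        refs = [
            (float(truth["line_px"][f][k]), f)
            for f in rb_d2.EXTENDED_REFERENCE_LINES_GHZ if f != 0.0
            for k in range(3)
        ]
        from lsbm.calibration import fit_dispersion

        calib = fit_dispersion(truth["anchor_px"], refs, quadratic=True)
        row = simulate_row_spectrum(WATER, cfg, 1e5)["noiseless"]
        m = process_row(row, calib, FitConfig())
        assert m.valid
        assert abs(m.shift - WATER.shift) < 1e-3


class TestSumOrders:
    def test_triple_identity_sum(self):
        s = doublet_spectrum()
        total = sum_orders([s, s, s])
        assert np.allclose(total.intensity, 3.0 * s.intensity)
        assert total.n_orders_summed == 9  # 3 spectra already marked as 3

    def test_permutation_invariance(self, calib, noiseless_water_row):
        specs = remap_to_linear(noiseless_water_row, calib, 0.1)
        a = sum_orders(specs)
        b = sum_orders(specs[::-1])
        assert np.array_equal(a.intensity, b.intensity, equal_nan=True)

    def test_grid_mismatch_rejected(self):
        a = doublet_spectrum(df=0.25)
        b = doublet_spectrum(df=0.5)
        with pytest.raises(InvalidParameterError):
            sum_orders([a, b, a])

    def test_too_few_orders_warns_or_raises(self):
        s = doublet_spectrum()
        s = LinearSpectrum(s.freq_ghz, s.intensity, n_orders_summed=1)
        with pytest.warns(UserWarning):
            sum_orders([s], min_orders=3)
        with pytest.raises(InvalidParameterError):
            sum_orders([s], min_orders=3, strict=True)


class TestFitSpectrum:
    def test_noiseless_lorentzian_recovered_to_1mhz(self):
        spec = doublet_spectrum(shift=5.05, fwhm=0.4, df=0.3)
        stokes, antistokes = fit_spectrum(
            spec, FitConfig(model_kind="lorentzian"))
        assert stokes.valid and antistokes.valid
        assert stokes.center == pytest.approx(-5.05, abs=1e-3)
        assert antistokes.center == pytest.approx(5.05, abs=1e-3)
        assert stokes.fwhm == pytest.approx(0.4, abs=1e-3)

    def test_flat_spectrum_flagged_invalid(self):
        grid = target_grid(15.15, 0.25)
        spec = LinearSpectrum(grid, np.full(grid.size, 7.0), n_orders_summed=3)
        stokes, antistokes = fit_spectrum(spec, FitConfig())
        assert not stokes.valid and not antistokes.valid

    @pytest.mark.parametrize(
        "sigma,kind,df_range",
        [
            (0.297, "broadened_brillouin", (0.25, 0.5)),  # instrument line shape
            (0.0, "lorentzian", (0.25, 0.25)),  # narrow line, fine sampling
        ],
    )
    def test_high_snr_mean_center_error_below_1mhz(self, sigma, kind, df_range):
        # the ~1 MHz fitter-accuracy figure: high-signal spectra, known centers
        rng = np.random.default_rng(7)
        errors = []
        for i in range(50):
            shift = rng.uniform(4.5, 5.5)
            df = rng.uniform(*df_range)
            spec = doublet_spectrum(shift=shift, amp=1e6, df=df, sigma=sigma,
                                    noise_sd=10.0, seed=i)
            stokes, antistokes = fit_spectrum(
                spec, FitConfig(model_kind=kind, instrument_sigma=sigma))
            assert stokes.valid and antistokes.valid
            shift_hat = 0.5 * (abs(stokes.center) + abs(antistokes.center))
            errors.append(abs(shift_hat - shift))
        assert np.mean(errors) * 1e3 <= 1.0  # MHz

    def test_stokes_antistokes_magnitudes_agree_at_high_snr(self):
        spec = doublet_spectrum(amp=1e6, sigma=0.297, df=0.25,
                                noise_sd=5.0, seed=3)
        stokes, antistokes = fit_spectrum(spec, FitConfig())
        assert abs(abs(stokes.center) - abs(antistokes.center)) < 2e-3


class TestShiftAndSnr:
    def _fit(self, center, valid=True):
        from lsbm.reconstruction import PeakFit

        return PeakFit(
            kind="lorentzian", amplitude=100.0, center=center, fwhm=0.4,
            background=(), instrument_sigma=0.0, fit_range=(2.0, 7.0),
            peak_height=100.0, residual_rms=1.0, r_squared=0.99,
            n_iterations=10, valid=valid,
        )

    def test_shift_is_mean_of_magnitudes(self):
        res = compute_shift(self._fit(-5.00), self._fit(5.02))
        assert res.shift_ghz == pytest.approx(5.01)
        assert res.valid and res.fallback is None

    def test_fallback_to_single_valid_fit(self):
        res = compute_shift(self._fit(-5.0, valid=False), self._fit(5.03))
        assert res.shift_ghz == pytest.approx(5.03)
        assert res.fallback == "antistokes"
        both_bad = compute_shift(self._fit(-5.0, False), self._fit(5.0, False))
        assert not both_bad.valid

    def test_snr_definition_20db(self):
        # amplitude 100 over residual sd 10 -> 20 dB
        fit = self._fit(5.05)
        grid = target_grid(15.15, 0.1)
        clean = fit.evaluate(grid)
        rng = np.random.default_rng(11)
        noisy = clean + rng.normal(0, 10.0, grid.size)
        spec = LinearSpectrum(grid, noisy, n_orders_summed=3)
        snr = compute_snr(spec, fit, (2.0, 7.0))
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_noiseless_perfect_fit_reports_inf(self):
        fit = self._fit(5.05)
        grid = target_grid(15.15, 0.1)
        spec = LinearSpectrum(grid, fit.evaluate(grid), n_orders_summed=3)
        assert compute_snr(spec, fit, (2.0, 7.0)) == math.inf

    def test_quadrupled_budget_gains_6db(self, spec_config, calib):
        def median_snr(budget, seeds):
            vals = []
            for s in seeds:
                frame = simulate_frame([WATER], spec_config, budget, rng_seed=s)
                m = process_row(frame.counts[0], calib, FitConfig())
                if m.valid:
                    vals.append(m.snr_db)
            return np.median(vals)

        lo = median_snr(500.0, range(20))
        hi = median_snr(2000.0, range(20, 40))
        assert hi - lo == pytest.approx(6.0, abs=2.0)


class TestProcessFrame:
    def test_uniform_frame_rows_cluster_around_mean(self, spec_config, calib):
        frame = simulate_frame([WATER] * 6, spec_config, 2000.0, rng_seed=9)
        ms = process_frame(frame, calib, FitConfig())
        shifts = np.array([m.shift for m in ms if m.valid])
        assert shifts.size == 6
        assert np.all(np.abs(shifts - shifts.mean()) < 0.05)

    def test_row_order_invariance(self, spec_config, calib):
        frame = simulate_frame([WATER] * 4, spec_config, 1500.0, rng_seed=10)
        fwd = process_frame(frame, calib, FitConfig())
        rev = process_frame(frame.counts[::-1], calib, FitConfig())
        for a, b in zip(fwd, rev[::-1]):
            assert a.shift == b.shift

    def test_batch_equals_reference_path(self, spec_config, calib):
        frame = simulate_frame([WATER] * 8, spec_config, 1500.0, rng_seed=12)
        batch = process_frame(frame, calib, FitConfig())
        for i in range(8):
            ref = process_row(frame.counts[i], calib, FitConfig(), row_index=i)
            assert abs(batch[i].shift - ref.shift) < 1e-4  # 0.1 MHz

    def test_bad_row_flagged_not_raised(self, spec_config, calib):
        frame = simulate_frame([WATER] * 2, spec_config, 1500.0, rng_seed=13)
        frame.counts[1] = 0.0  # dead row
        ms = process_frame(frame, calib, FitConfig())
        assert ms[0].valid and not ms[1].valid


class TestCharacterization:
    def test_precision_of_constant_list_is_zero(self):
        assert measure_precision([5.05] * 10) == pytest.approx(0.0, abs=1e-9)

    def test_precision_matches_known_distribution(self):
        rng = np.random.default_rng(21)
        shifts = rng.normal(5.05, 0.010, 50)  # 10 MHz sd
        assert measure_precision(shifts) == pytest.approx(10.0, rel=0.35)

    def test_precision_needs_two_measurements(self):
        with pytest.raises(InvalidParameterError):
            measure_precision([5.05])

    def test_resolution_recovered_within_grid_step(self, spec_config, calib):
        from lsbm import rb_d2
        from lsbm.simulator import simulate_calibration_frame

        frame = simulate_calibration_frame(
            spec_config, rb_d2.DEFAULT_REFERENCE_LINES_GHZ)
        kernel_fwhm = spec_config.instrument_kernel.fwhm
        for df in (0.1, 0.2):
            summed = sum_orders(remap_to_linear(frame.counts[0], calib, df))
            res = measure_spectral_resolution(summed)
            assert res.reliable
            assert abs(res.fwhm_ghz - kernel_fwhm) <= df

    def test_delta_like_peak_flagged_unreliable(self):
        grid = target_grid(15.15, 0.5)
        y = np.zeros(grid.size)
        y[np.argmin(np.abs(grid))] = 1000.0
        spec = LinearSpectrum(grid, y, n_orders_summed=3)
        res = measure_spectral_resolution(spec)
        assert not res.reliable

    def test_no_elastic_peak_is_error(self):
        from lsbm.errors import DetectionError

        spec = doublet_spectrum()  # notch-suppressed: nothing near 0
        with pytest.raises(DetectionError):
            measure_spectral_resolution(spec)
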