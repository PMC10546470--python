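"""Localization MLE, spectral window, centroid and Gaussian fits."""

import numpy as np
import pytest
from scipy.special import ndtr

from dwpsim.analysis import (SpectralWindow, correct_dispersion_nonuniformity,
                             estimate_precision, extract_spectral_window,
                             fit_spectrum, mle_localize, spectral_centroid,
                             _nll_and_grad)
from dwpsim.detector import DetectorModel, accumulate, read_out
from dwpsim.optics import default_calibration, dispersion_nm_per_px


def _pixel_gaussian_roi(nx, ny, x0, y0, sigma, n, b):
    """Exact expected counts of a pixel-integrated Gaussian + background."""
    xe = np.arange(nx + 1)
    ye = np.arange(ny + 1)
    gx = np.diff(ndtr((xe - x0) / sigma))
    gy = np.diff(ndtr((ye - y0) / sigma))
    return n * np.outer(gy, gx) + b


@pytest.fixture
def det():
    return DetectorModel(shape=(15, 15))


class TestMleLocalize:
    def test_noiseless_roi_recovered_to_hundredth_pixel(self, det):
        expected = _pixel_gaussian_roi(15, 15, 7.31, 7.87, 1.1, 1200.0, 15.0)
        adu = expected * det.adu_per_photon  # noiseless ADU frame
        res = mle_localize(adu, det)
        assert res.converged
        assert res.x_hat / det.ax == pytest.approx(7.31, abs=0.01)
        assert res.y_hat / det.ay == pytest.approx(7.87, abs=0.01)
        assert res.sigma_hat / det.ax == pytest.approx(1.1, abs=0.02)
        assert res.n_hat == pytest.approx(1200.0, rel=0.02)

    def test_optimizer_beats_exhaustive_position_grid(self, det, rng):
        # the returned optimum must dominate a dense (x, y) grid search
        # of the same likelihood with the remaining parameters held at
        # the fitted values
        for _ in range(20):
            x0, y0 = rng.uniform(3.0, 6.0, size=2)
            S, _ = accumulate(rng.normal(x0 * 160, 160, 800),
                              rng.normal(y0 * 160, 160, 800),
                              det, shape=(9, 9))
            frame = read_out(S, det, rng)
            res = mle_localize(frame.Z, det)
            e = frame.Z / det.adu_per_photon + det.bro**2
            xe = np.arange(10.0)
            grid = np.linspace(-0.5, 0.5, 21)
            best = min(
                _nll_and_grad(
                    np.array([res.x_hat / 160 + dx, res.y_hat / 160 + dy,
                              res.sigma_hat / 160, res.n_hat, res.b_hat]),
                    e, xe, xe)[0]
                for dx in grid for dy in grid)
            assert res.nll <= best + 1e-6

    def test_degenerate_all_zero_roi_rejected(self, det):
        with pytest.raises(ValueError):
            mle_localize(np.full((15, 15), -100.0), det)

    def test_precision_approaches_theory_bound(self, det, rng):
        from dwpsim.theory import TheoryParams, localization_precision
        errs = []
        for _ in range(400):
            x0 = (7.5 + rng.uniform(-0.5, 0.5)) * 160.0
            y0 = (7.5 + rng.uniform(-0.5, 0.5)) * 160.0
            S, _ = accumulate(rng.normal(x0, 160.0, 2000),
                              rng.normal(y0, 160.0, 2000), det)
            res = mle_localize(read_out(S, det, rng).Z, det)
            errs.append(res.x_hat - x0)
        mc = np.std(errs, ddof=1)
        th = float(localization_precision(
            TheoryParams(n_photons=2000, bbg=15.0)))
        assert mc == pytest.approx(th, rel=0.15)


def _window_linear(profile2d, lo=450.0, a_lam=5.0):
    ncols = profile2d.shape[1]
    lam = lo + (np.arange(ncols) + 0.5) * a_lam
    return SpectralWindow(image=profile2d, lam_axis=lam,
                          nm_per_px=np.full(ncols, a_lam))


class TestSpectralCentroid:
    def test_symmetric_profile_gives_exact_centre(self):
        lam = 450.0 + (np.arange(70) + 0.5) * 5.0
        w = np.exp(-0.5 * ((lam - 650.0) / 20.0) ** 2)
        win = _window_linear(w[None, :])
        res = spectral_centroid(win)
        assert res.mu_hat == pytest.approx(650.0, abs=1e-9)

    def test_all_zero_profile_rejected(self):
        win = _window_linear(np.zeros((1, 70)))
        with pytest.raises(ValueError):
            spectral_centroid(win)

    def test_unsubtracted_background_pulls_toward_window_mean(self):
        lam = 450.0 + (np.arange(70) + 0.5) * 5.0
        w = np.exp(-0.5 * ((lam - 700.0) / 20.0) ** 2)
        clean = spectral_centroid(_window_linear(w[None, :])).mu_hat
        lifted = spectral_centroid(_window_linear(w[None, :] + 0.2)).mu_hat
        window_mean = lam.mean()
        assert clean == pytest.approx(700.0, abs=1e-3)  # asymmetric tail cut
        assert clean > lifted > window_mean

    def test_negative_weight_conventions(self):
        img = np.array([[1.0, -0.5, 2.0, 1.0]])
        win = SpectralWindow(image=img,
                             lam_axis=np.array([500.0, 550.0, 600.0, 650.0]),
                             nm_per_px=np.full(4, 10.0))
        mu_clip = spectral_centroid(win, negative_weights="clip").mu_hat
        mu_keep = spectral_centroid(win, negative_weights="keep").mu_hat
        assert mu_clip == pytest.approx((500 + 2 * 600 + 650) / 4.0)
        assert mu_keep == pytest.approx(
            (500 - 0.5 * 550 + 2 * 600 + 650) / 3.5)


class TestDispersionCorrection:
    def _dwp_axis(self, n=120):
        cal = default_calibration()
        from dwpsim.optics import wavelength_to_pixel, pixel_to_wavelength
        px0 = wavelength_to_pixel(450.0, cal)
        cols = px0 + np.arange(n) + 0.5
        lam = pixel_to_wavelength(cols, cal)
        lam = lam[lam <= 800.0]
        return lam, dispersion_nm_per_px(lam, cal)

    def test_uniform_source_flattens_after_correction(self):
        # a spectrally uniform source is rendered non-uniform by the
        # DWP's varying dispersion; dividing by nm/px restores flatness
        lam, nmpp = self._dwp_axis()
        counts = nmpp.copy()  # photons per column ~ wavelength span
        corrected = correct_dispersion_nonuniformity(counts, nmpp)
        assert counts.std() / counts.mean() > 0.3
        assert corrected.std() / corrected.mean() < 1e-6

    def test_linear_dispersion_correction_is_constant(self):
        prof = np.array([1.0, 2.0, 3.0])
        out = correct_dispersion_nonuniformity(prof, np.full(3, 5.0))
        assert np.allclose(out * 5.0, prof)

    def test_uncorrected_fit_biased_toward_red(self):
        # with stronger dispersion in the blue, equal spectral density
        # yields fewer counts per blue pixel; fitting without the
        # correction therefore biases the peak to longer wavelengths
        lam, nmpp = self._dwp_axis()
        density = np.exp(-0.5 * ((lam - 680.0) / 17.4) ** 2)
        counts = density * nmpp
        win = SpectralWindow(image=counts[None, :], lam_axis=lam,
                             nm_per_px=nmpp)
        mu_corr = fit_spectrum(win, mode="FIT_1D",
                               correct_nonuniformity=True).mu_hat
        mu_raw = fit_spectrum(win, mode="FIT_1D",
                              correct_nonuniformity=False).mu_hat
        assert mu_corr == pytest.approx(680.0, abs=0.2)
        assert mu_raw > mu_corr + 0.5


class TestFitSpectrum:
    def test_noiseless_profile_exact_recovery(self):
        lam = 450.0 + (np.arange(70) + 0.5) * 5.0
        true = dict(A=40.0, mu=672.0, s=18.0, c=2.0)
        prof = true["A"] * np.exp(-0.5 * ((lam - true["mu"]) / true["s"])**2) \
            + true["c"]
        win = _window_linear((prof / 5.0)[None, :])  # counts -> density
        res = fit_spectrum(win, mode="FIT_1D", correct_nonuniformity=True)
        assert res.converged
        assert res.mu_hat == pytest.approx(672.0, rel=1e-6)
        assert res.sigma_lam_hat == pytest.approx(18.0, rel=1e-6)

    def test_noiseless_2d_recovery(self):
        lam = 450.0 + (np.arange(70) + 0.5) * 5.0
        rows = (np.arange(7) + 0.5)[:, None]
        img = 30.0 * np.exp(-0.5 * ((lam[None, :] - 660.0) / 17.0) ** 2
                            - 0.5 * ((rows - 3.5) / 1.0) ** 2) + 1.0
        win = _window_linear(img)
        res = fit_spectrum(win, mode="FIT_2D")
        assert res.converged
        assert res.mu_hat == pytest.approx(660.0, abs=1e-4)
        assert res.sigma_lam_hat == pytest.approx(17.0, abs=1e-3)

    def test_unknown_mode_rejected(self):
        win = _window_linear(np.ones((1, 10)))
        with pytest.raises(ValueError):
            fit_spectrum(win, mode="FIT_3D")


class TestExtractWindow:
    def test_columns_map_to_analytic_axis(self, det):
        frame = np.zeros((7, 80))
        win = extract_spectral_window(
            frame, det, lambda c: 440.0 + np.asarray(c) * 5.0,
            band=(450.0, 800.0))
        assert np.all(np.diff(win.lam_axis) > 0)
        assert win.lam_axis[0] >= 450.0 and win.lam_axis[-1] <= 800.0
        assert not win.truncated

    def test_band_outside_frame_rejected(self, det):
        with pytest.raises(ValueError):
            extract_spectral_window(np.zeros((7, 10)), det,
                                    lambda c: np.asarray(c) + 2000.0)

    def test_row_truncation_flagged(self, det):
        win = extract_spectral_window(
            np.zeros((3, 80)), det, lambda c: 440.0 + np.asarray(c) * 5.0,
            row_halfwidth=5)
        assert win.truncated


class TestEstimatePrecision:
    def test_identical_repeats_give_zero(self):
        pe = estimate_precision(np.full(100, 3.2), 3.2)
        assert pe.precision == 0.0 and pe.bias == 0.0

    def test_iid_normal_sd_recovered_within_sampling_error(self, rng):
        # sampling sd of an sd estimate over R repeats ~ s/sqrt(2R)
        s = 4.0
        est = rng.normal(0.0, s, 20_000)
        pe = estimate_precision(est, 0.0)
        assert pe.precision == pytest.approx(s, rel=0.01)

    def test_nonconverged_excluded_and_counted(self):
        est = np.array([1.0, 2.0, 3.0, 100.0])
        ok = np.array([True, True, True, False])
        pe = estimate_precision(est, 0.0, converged=ok)
        assert pe.n_used == 3 and pe.n_total == 4
        assert pe.convergence_rate == 0.75

    def test_too_few_converged_rejected(self):
        with pytest.raises(ValueError):
            estimate_precision(np.array([1.0, np.nan]), 0.0)
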