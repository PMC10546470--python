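"""Estimation: MLE localization, spectral centroid and Gaussian fits.

Localization maximizes the Poisson log-likelihood of a pixel-integrated
2D Gaussian plus flat background on the gain-normalized spatial ROI.
Gain normalization before a Poisson fit is an approximation — the
EM-amplified data are Gamma-mixed, which inflates the estimator
variance by exactly the excess-noise factor the theory module applies.

Spectral estimation works on a background-subtracted spectral window
whose columns carry a wavelength axis from the dispersion calibration:
either an intensity-weighted centroid or a least-squares Gaussian fit
(1D profile or full 2D subimage). For the nonuniform DWP dispersion the
window is first divided by the local nm-per-pixel density so a
spectrally flat source gives a flat profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import ndtr

from .detector import DetectorModel, gain_normalize

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class LocalizationResult:
    x_hat: float          # nm, relative to the ROI origin
    y_hat: float
    sigma_hat: float      # fitted PSF sd, nm
    n_hat: float          # fitted photon count
    b_hat: float          # fitted background photons per pixel
    converged: bool
    nll: float


@dataclass
class SpectralResult:
    mu_hat: float             # spectral peak, nm
    sigma_lam_hat: float      # spectral width (sd convention), nm
    method: str               # CENTROID | FIT_1D | FIT_2D
    converged: bool


# ---------------------------------------------------------------------------
# MLE localization
# ---------------------------------------------------------------------------

def _gauss_bin_masses(edges, mu, sigma):
    """Per-bin masses of N(mu, sigma^2) over unit-pixel edges, plus the
    phi values at the edges needed for analytic gradients."""
    z = (edges - mu) / sigma
    Phi = ndtr(z)
    phi = np.exp(-0.5 * z * z) / _SQRT2PI
    G = np.diff(Phi)
    return G, z, phi


def _nll_and_grad(p, e, xedges, yedges):
    x0, y0, sigma, n, b = p
    Gx, zx, phx = _gauss_bin_masses(xedges, x0, sigma)
    Gy, zy, phy = _gauss_bin_masses(yedges, y0, sigma)
    rate = n * np.outer(Gy, Gx) + b
    w = 1.0 - e / rate
    nll = float(np.sum(rate - e * np.log(rate)))
    # d G / d mu = -(phi_hi - phi_lo)/sigma ; d G / d sigma = -(z_hi phi_hi - z_lo phi_lo)/sigma
    dGx_dx = -np.diff(phx) / sigma
    dGy_dy = -np.diff(phy) / sigma
    dGx_ds = -np.diff(zx * phx) / sigma
    dGy_ds = -np.diff(zy * phy) / sigma
    g_x0 = n * float(np.sum(w * np.outer(Gy, dGx_dx)))
    g_y0 = n * float(np.sum(w * np.outer(dGy_dy, Gx)))
    g_s = n * float(np.sum(w * (np.outer(Gy, dGx_ds) + np.outer(dGy_ds, Gx))))
    g_n = float(np.sum(w * np.outer(Gy, Gx)))
    g_b = float(np.sum(w))
    return nll, np.array([g_x0, g_y0, g_s, g_n, g_b])


def moment_initialization(e: np.ndarray):
    """Centroid + second-moment starting point for the MLE."""
    ny, nx = e.shape
    border = np.concatenate([e[0], e[-1], e[1:-1, 0], e[1:-1, -1]])
    b0 = max(float(np.median(border)), 1e-3)
    w = np.clip(e - b0, 0.0, None)
    total = float(w.sum())
    if total <= 0:
        w = np.clip(e, 0.0, None) + 1e-12
        total = float(w.sum())
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    x0 = float((w.sum(axis=0) * xs).sum() / total)
    y0 = float((w.sum(axis=1) * ys).sum() / total)
    var = ((w.sum(axis=0) * (xs - x0) ** 2).sum()
           + (w.sum(axis=1) * (ys - y0) ** 2).sum()) / (2.0 * total)
    s0 = float(np.sqrt(max(var, 0.09)))
    return x0, y0, min(s0, min(nx, ny) / 2.0), max(total, 1.0), b0


def mle_localize(spatial_roi_adu: np.ndarray, detector: DetectorModel,
                 init: Optional[tuple] = None,
                 subtracted: bool = False) -> LocalizationResult:
    """Fit a pixel-integrated 2D Gaussian + flat background by MLE.

    ``spatial_roi_adu`` is the raw ROI in ADU (or background-subtracted
    if ``subtracted``). The fit runs on gain-normalized photon
    equivalents in pixel units; the result is converted to nm relative
    to the ROI origin (pixel (0, 0) corner).
    """
    e = gain_normalize(spatial_roi_adu, detector)
    if subtracted:
        e = e + detector.bbg  # restore the mean level for the Poisson model
    # Fold Gaussian readout noise into the Poisson model by adding its
    # photon-equivalent variance to data and (via the fitted flat
    # background) to the model. Without this, readout-dominated frames
    # (bbg ~ 0) have negative pixels that send the log-likelihood to
    # -inf as the fitted background approaches zero.
    bro_ph = detector.bro if detector.readout_convention == "table1" \
        else detector.bro / detector.em_gain
    e = e + bro_ph**2
    if not np.any(e > 0):
        raise ValueError("degenerate ROI: no positive signal")
    ny, nx = e.shape
    xedges = np.arange(nx + 1, dtype=float)
    yedges = np.arange(ny + 1, dtype=float)
    p0 = np.array(moment_initialization(e) if init is None else init, dtype=float)
    bounds = [(-2.0, nx + 2.0), (-2.0, ny + 2.0),
              (0.3, max(nx, ny)), (1.0, None), (1e-6, None)]
    res = optimize.minimize(
        _nll_and_grad, p0, args=(e, xedges, yedges), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8})
    x0, y0, sigma, n, b = res.x
    interior = (0.0 < x0 < nx) and (0.0 < y0 < ny)
    return LocalizationResult(
        x_hat=float(x0 * detector.ax), y_hat=float(y0 * detector.ay),
        sigma_hat=float(sigma * detector.ax), n_hat=float(n), b_hat=float(b),
        converged=bool(res.success and interior), nll=float(res.fun))


# ---------------------------------------------------------------------------
# spectral window
# ---------------------------------------------------------------------------

@dataclass
class SpectralWindow:
    """A spectral subimage with per-column wavelength axis.

    ``image`` is gain-normalized (photon equivalents), background-
    subtracted. ``lam_axis`` gives the wavelength at each column centre
    and is strictly increasing; ``nm_per_px`` is the local dispersion
    density used for nonuniformity correction. ``truncated`` flags a
    window clipped at the sensor bounds.
    """
    image: np.ndarray
    lam_axis: np.ndarray
    nm_per_px: np.ndarray
    truncated: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.lam_axis) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")

    def profile(self) -> np.ndarray:
        """1D spectral profile: image summed along y."""
        return self.image.sum(axis=0)


def extract_spectral_window(frame_adu: np.ndarray, detector: DetectorModel,
                            wavelength_of_column, band=(450.0, 800.0),
                            row_center: Optional[float] = None,
                            row_halfwidth: int = 3) -> SpectralWindow:
    """Cut the spectral subimage for one localization.

    ``wavelength_of_column`` maps absolute column index (pixel centre)
    to wavelength; it comes from the calibrated dispersion referenced
    to the zeroth-order position. Columns whose wavelength falls in
    ``band`` and rows within ``row_halfwidth`` of ``row_center`` are
    kept.
    """
    nrows, ncols = frame_adu.shape
    cols = np.arange(ncols)
    lam = np.asarray(wavelength_of_column(cols + 0.5), dtype=float)
    keep = (lam >= band[0]) & (lam <= band[1])
    if not np.any(keep):
        raise ValueError("no columns fall inside the spectral band")
    r0 = (nrows - 1) / 2.0 if row_center is None else row_center
    rlo = int(np.floor(r0 - row_halfwidth + 0.5))
    rhi = int(np.floor(r0 + row_halfwidth + 0.5)) + 1
    truncated = rlo < 0 or rhi > nrows
    rlo, rhi = max(rlo, 0), min(rhi, nrows)
    sub = frame_adu[rlo:rhi][:, keep]
    lam_axis = lam[keep]
    # local nm/px from the wavelength axis itself
    nm_per_px = np.gradient(lam_axis)
    e = gain_normalize(sub, detector) - detector.bbg
    return SpectralWindow(image=e, lam_axis=lam_axis, nm_per_px=nm_per_px,
                          truncated=truncated)


def correct_dispersion_nonuniformity(profile: np.ndarray,
                                     nm_per_px: np.ndarray) -> np.ndarray:
    """Divide each column by the local nm-per-pixel dispersion density.

    A spectrally uniform source produces per-column counts proportional
    to the wavelength span of the column; dividing by that span yields
    a flat corrected profile (spectral density per nm). For a linear
    dispersion the correction is a global constant.
    """
    nm_per_px = np.asarray(nm_per_px, dtype=float)
    if np.any(nm_per_px <= 0):
        raise ValueError("dispersion density must be positive")
    return np.asarray(profile, dtype=float) / nm_per_px


# ---------------------------------------------------------------------------
# spectral estimators
# ---------------------------------------------------------------------------

def spectral_centroid(window: SpectralWindow,
                      negative_weights: str = "clip") -> SpectralResult:
    """Intensity-weighted mean wavelength of the detected spectrum.

    Weights are the per-column photon counts; negative values left by
    background subtraction are clipped at zero by default
    (``negative_weights="keep"`` retains them).
    """
    w = window.profile()
    if negative_weights == "clip":
        w = np.clip(w, 0.0, None)
    elif negative_weights != "keep":
        raise ValueError("negative_weights must be 'clip' or 'keep'")
    total = float(w.sum())
    if total <= 0:
        raise ValueError("undefined centroid: non-positive total weight")
    mu = float((w * window.lam_axis).sum() / total)
    var = float((w * (window.lam_axis - mu) ** 2).sum() / total)
    return SpectralResult(mu_hat=mu, sigma_lam_hat=float(np.sqrt(max(var, 0.0))),
                          method="CENTROID", converged=True)


def _centroid_init(window: SpectralWindow):
    """Robust peak/width starting point: argmax of a smoothed profile.

    The raw centroid is badly biased toward the window mean at high
    background, which can put a least-squares fit in the wrong basin;
    the peak of a lightly smoothed profile is a much safer anchor. The
    width is then a second moment taken only near that peak.
    """
    w = np.clip(window.profile(), 0.0, None)
    lam = window.lam_axis
    # Gaussian smoothing in wavelength units (sigma ~ typical emission
    # width) so the kernel stays matched where the dispersion is strong
    # and the spectrum spreads over many columns.
    # noise-normalized matched filter on the wavelength grid: per-column
    # noise variance is constant, so dividing by sqrt(sum K^2) equalizes
    # the false-alarm rate between strongly and weakly dispersed regions
    kern = np.exp(-0.5 * ((lam[:, None] - lam[None, :]) / 15.0) ** 2)
    ws = (kern @ w) / np.sqrt((kern**2).sum(axis=1))
    mu0 = float(lam[int(np.argmax(ws))])
    near = np.abs(lam - mu0) <= 60.0
    wn = w[near] + 1e-12
    mu_n = float((wn * lam[near]).sum() / wn.sum())
    var0 = float((wn * (lam[near] - mu_n) ** 2).sum() / wn.sum())
    return mu0, float(np.sqrt(max(min(var0, 3600.0), 1.0)))


def fit_spectrum(window: SpectralWindow, mode: str = "FIT_2D",
                 init: Optional[tuple] = None,
                 correct_nonuniformity: bool = True) -> SpectralResult:
    """Least-squares Gaussian (+ offset) fit of the spectral window.

    FIT_1D fits ``A*exp(-(lam-mu)^2/2*sigma^2) + c`` to the y-summed,
    dispersion-corrected profile. FIT_2D fits the separable bivariate
    Gaussian (amplitude, mu_lam, sigma_lam, y-centre, sigma_y, offset)
    on the corrected 2D subimage, which uses both dimensions for noise
    rejection.
    """
    lam = window.lam_axis
    if init is None:
        mu0, s0 = _centroid_init(window)
    else:
        mu0, s0 = init
    lam_lo, lam_hi = float(lam[0]), float(lam[-1])
    mu0 = min(max(mu0, lam_lo), lam_hi)
    s0 = min(max(s0, 1.0), (lam_hi - lam_lo))

    if mode == "FIT_1D":
        y = correct_dispersion_nonuniformity(window.profile(), window.nm_per_px) \
            if correct_nonuniformity else window.profile()
        a0 = max(float(y.max()), 1e-6)

        def model1d(p):
            A, mu, s, c = p
            return A * np.exp(-0.5 * ((lam - mu) / s) ** 2) + c

        def resid(p):
            return model1d(p) - y

        p0 = np.array([a0, mu0, s0, float(np.median(y))])
        # the peak may move only within one emission-bandwidth of the
        # robust init: keeps low-SNR fits out of background basins
        lb = [0.0, max(lam_lo, mu0 - 60.0), 0.3, -np.inf]
        ub = [np.inf, min(lam_hi, mu0 + 60.0), lam_hi - lam_lo, np.inf]
        res = optimize.least_squares(resid, p0, bounds=(lb, ub),
                                     method="trf", max_nfev=400)
        A, mu, s, c = res.x
        bad = _fit_quality_bad(A, mu, s, lam_lo, lam_hi)
        return SpectralResult(float(mu), float(s), "FIT_1D",
                              bool(res.success and not bad))

    if mode != "FIT_2D":
        raise ValueError("mode must be 'FIT_1D' or 'FIT_2D'")

    img = window.image / window.nm_per_px[None, :] if correct_nonuniformity \
        else window.image
    nrows = img.shape[0]
    rows = (np.arange(nrows) + 0.5)[:, None]
    lam2 = lam[None, :]
    a0 = max(float(img.max()), 1e-6)
    y00 = nrows / 2.0
    sy0 = max(nrows / 4.0, 0.5)

    def resid2(p):
        A, mu, s, yc, sy, c = p
        g = A * np.exp(-0.5 * ((lam2 - mu) / s) ** 2
                       - 0.5 * ((rows - yc) / sy) ** 2) + c
        return (g - img).ravel()

    p0 = np.array([a0, mu0, s0, y00, sy0, float(np.median(img))])
    lb = [0.0, max(lam_lo, mu0 - 60.0), 0.3, -1.0, 0.2, -np.inf]
    ub = [np.inf, min(lam_hi, mu0 + 60.0), lam_hi - lam_lo,
          nrows + 1.0, nrows * 2.0, np.inf]
    res = optimize.least_squares(resid2, p0, bounds=(lb, ub),
                                 method="trf", max_nfev=400)
    A, mu, s, yc, sy, c = res.x
    bad = _fit_quality_bad(A, mu, s, lam_lo, lam_hi)
    return SpectralResult(float(mu), float(s), "FIT_2D",
                          bool(res.success and not bad))


def _fit_quality_bad(amplitude, mu, sigma, lam_lo, lam_hi) -> bool:
    """Reject non-physical spectral fits: width pinned at its bounds,
    vanishing amplitude, or a peak driven onto the window edge."""
    span = lam_hi - lam_lo
    return bool(sigma <= 0.31 or sigma >= 0.99 * span
                or amplitude <= 1e-9
                or mu <= lam_lo + 1.0 or mu >= lam_hi - 1.0)


# ---------------------------------------------------------------------------
# precision over repeats
# ---------------------------------------------------------------------------

@dataclass
class PrecisionEstimate:
    precision: float       # sample sd of (estimate - truth)
    bias: float            # mean of (estimate - truth)
    n_used: int
    n_total: int

    @property
    def convergence_rate(self) -> float:
        return self.n_used / self.n_total if self.n_total else 0.0


def estimate_precision(estimates, truths, converged=None,
                       min_converged: int = 2) -> PrecisionEstimate:
    """Standard deviation of estimation errors over repeated events.

    Errors are taken against the per-repeat ground truth, so subpixel
    placement offsets drop out; non-converged repeats are excluded and
    counted.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.broadcast_to(np.asarray(truths, dtype=float), est.shape)
    ok = np.ones(est.shape, dtype=bool) if converged is None \
        else np.asarray(converged, dtype=bool)
    ok = ok & np.isfinite(est)
    n_used = int(ok.sum())
    if n_used < min_converged:
        raise ValueError(f"only {n_used} converged repeats (< {min_converged})")
    err = est[ok] - tru[ok]
    return PrecisionEstimate(precision=float(np.std(err, ddof=1)),
                             bias=float(np.mean(err)),
                             n_used=n_used, n_total=int(est.size))
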