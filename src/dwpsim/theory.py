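"""Closed-form localization and spectral precision.

These are the analytic benchmarks the Monte Carlo engine is validated
against: the Cramér–Rao-style bound for maximum-likelihood localization
of a pixelated 2D Gaussian spot on a uniform background, and the
centroid-based spectral-precision formula for a linearly dispersed
Gaussian emission spectrum.

Both calculators optionally include the EMCCD excess-noise correction
``FEM`` (the electron-multiplying register doubles the variance of the
photon signal), which must be applied when comparing against frames
rendered with Gamma-distributed gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# FWHM of a Gaussian = C_FWHM * (standard deviation)
C_FWHM: float = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Excess-noise (electron-multiplying) variance factor of an EMCCD.
FEM_DEFAULT: float = 2.0


@dataclass
class TheoryParams:
    """Parameter set for the analytic precision formulas.

    Attributes
    ----------
    sigma_x, sigma_y : float
        PSF standard deviation along x / y, nm (object space).
    sigma_lam_fwhm : float
        FWHM of the emission spectrum, nm.
    ax, ay : float
        Pixel size, nm/px (object space).
    a_lam : float
        Spectral dispersion, nm of wavelength per pixel.
    n_photons : float
        Photons detected in the analyzed channel.
    bbg : float
        Mean background photons per pixel.
    bro : float
        Readout-noise standard deviation in photon-equivalent units
        (the detector model injects readout noise scaled by gain/ADU,
        so 1.9 e- acts as 1.9 photons per pixel after normalization).
    fem : float
        Excess-noise variance factor of the EM register (2 for EMCCDs).
    """

    sigma_x: float = 160.0
    sigma_y: float = 160.0
    sigma_lam_fwhm: float = 41.0
    ax: float = 160.0
    ay: float = 160.0
    a_lam: float = 5.0
    n_photons: float = 700.0
    bbg: float = 15.0
    bro: float = 1.9
    fem: float = FEM_DEFAULT


def background_correction_factor(params: TheoryParams, n=None, bbg=None):
    """tau, the background correction factor of the localization bound.

    tau = 2*pi*(bbg + bro^2) * (sigma_x^2 + ax^2/12) / (N * ax^2)
    """
    p = params
    n = p.n_photons if n is None else np.asarray(n, dtype=float)
    bbg = p.bbg if bbg is None else np.asarray(bbg, dtype=float)
    sa2 = p.sigma_x**2 + p.ax**2 / 12.0
    return 2.0 * np.pi * (bbg + p.bro**2) * sa2 / (n * p.ax**2)


def localization_precision(params: TheoryParams, n=None, bbg=None,
                           apply_fem: bool = True):
    """Localization precision Δx (nm) for MLE fitting of a Gaussian spot.

    Δx² = (σx² + ax²/12)/N · (1 + 4τ + √(2τ/(1+4τ)))

    With ``apply_fem`` the variance is multiplied by the EMCCD
    excess-noise factor, so the returned precision is √FEM larger than
    the bare bound. ``n`` and ``bbg`` may be arrays for sweeps.
    """
    p = params
    n_arr = np.asarray(p.n_photons if n is None else n, dtype=float)
    if np.any(n_arr <= 0):
        raise ValueError("photon count must be positive")
    tau = background_correction_factor(p, n=n_arr, bbg=bbg)
    sa2 = p.sigma_x**2 + p.ax**2 / 12.0
    factor = 1.0 + 4.0 * tau + np.sqrt(2.0 * tau / (1.0 + 4.0 * tau))
    var = sa2 / n_arr * factor
    if apply_fem:
        var = var * p.fem
    return np.sqrt(var)


def spectral_precision(params: TheoryParams, n=None, bbg=None,
                       apply_fem: bool = True):
    """Spectral precision Δμλ (nm) for the spectral-centroid estimator.

    Δμλ² = FEM·(σλ²/(c²N) + 1024·bbg·(σλ/c)³·(σy/ay)³/(aλ·N²))
           + 1024·bro²·(σλ/c)³·(σy/ay)³/(aλ·N²) + aλ²/12

    where σλ is the spectral FWHM, c converts FWHM to standard
    deviation, σy/ay is the PSF width in pixels and aλ the linear
    spectral dispersion. The EM excess noise multiplies the variance of
    every photon-derived term once (factor FEM = 2), the same
    convention as the localization bound; readout noise sees no EM
    gain and the aλ²/12 spectral-discretization floor is noise-free.
    Assumes a uniform dispersion and a Gaussian spectrum. Without
    ``apply_fem`` the factor is set to 1.
    """
    p = params
    n_arr = np.asarray(p.n_photons if n is None else n, dtype=float)
    if np.any(n_arr <= 0):
        raise ValueError("photon count must be positive")
    bbg_arr = np.asarray(p.bbg if bbg is None else bbg, dtype=float)
    fem = p.fem if apply_fem else 1.0
    sl_sd = p.sigma_lam_fwhm / C_FWHM
    sy_px = p.sigma_y / p.ay
    noise_kernel = 1024.0 * sl_sd**3 * sy_px**3 / (p.a_lam * n_arr**2)
    var = (fem * (sl_sd**2 / n_arr + bbg_arr * noise_kernel)
           + p.bro**2 * noise_kernel
           + p.a_lam**2 / 12.0)
    return np.sqrt(var)
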