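"""Ground-truth photon emission: counts, wavelengths and PSF positions.

A single blinking event of a fluorophore is modelled as N photons
emitted in one frame. N is either a fixed number or a lognormal draw
(SMLM photon-count histograms are well described by a lognormal). Each
photon carries a wavelength sampled from the emission spectrum and a
lateral position sampled from a 2D Gaussian approximation of the Airy
disc, whose width scales linearly with wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Simulated wavelength band, nm. The dispersion model is valid here.
BAND_NM = (400.0, 900.0)

#: Default Gaussian-PSF width coefficient k in sigma_psf = k * lambda / NA.
#: With NA = 1.49 this gives ~160 nm (one object-space pixel) at 680 nm.
PSF_SIGMA_COEFF = 0.35

NA_DEFAULT = 1.49


def psf_sigma(lam_nm, na: float = NA_DEFAULT, coeff: float = PSF_SIGMA_COEFF):
    """Gaussian PSF standard deviation (nm) at wavelength ``lam_nm``."""
    return coeff * np.asarray(lam_nm, dtype=float) / na


# ---------------------------------------------------------------------------
# photon-count laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedCount:
    """Deterministic photon count."""
    n: int

    def __post_init__(self):
        if not np.isfinite(self.n) or self.n < 1:
            raise ValueError("fixed photon count must be a finite integer >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        return int(self.n)


@dataclass(frozen=True)
class LognormalCount:
    """Photon count N with ln N ~ Normal(mu_log, sigma_log^2), rounded."""
    mu_log: float
    sigma_log: float

    def __post_init__(self):
        if not np.isfinite(self.mu_log) or not np.isfinite(self.sigma_log):
            raise ValueError("lognormal parameters must be finite")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")

    def sample(self, rng: np.random.Generator) -> int:
        return int(round(float(np.exp(rng.normal(self.mu_log, self.sigma_log)))))


def sample_photon_count(count_law, rng: np.random.Generator) -> int:
    """Draw one integer photon count from a count law."""
    n = count_law.sample(rng)
    if n < 0:
        raise ValueError("photon count must be non-negative")
    return n


# ---------------------------------------------------------------------------
# emission spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianSpectrum:
    """Gaussian emission spectrum given by peak (nm) and FWHM (nm).

    Samples are truncated to the simulated band by resampling, which is
    immaterial for realistic fluorophore spectra (the band edges sit
    many standard deviations from the peak).
    """
    peak_nm: float
    fwhm_nm: float

    def __post_init__(self):
        if not (BAND_NM[0] <= self.peak_nm <= BAND_NM[1]):
            raise ValueError(f"peak_nm must lie in {BAND_NM}")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lam = rng.normal(self.peak_nm, self.sigma_nm, size=n)
        bad = (lam < BAND_NM[0]) | (lam > BAND_NM[1])
        while np.any(bad):
            lam[bad] = rng.normal(self.peak_nm, self.sigma_nm, size=int(bad.sum()))
            bad = (lam < BAND_NM[0]) | (lam > BAND_NM[1])
        return lam


@dataclass(frozen=True)
class TabulatedSpectrum:
    """Emission spectrum tabulated on a strictly increasing nm grid.

    Sampling uses the inverse CDF of the linearly interpolated density.
    Weights are normalized to sum to one on construction.
    """
    wavelength_nm: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        w_nm = np.asarray(self.wavelength_nm, dtype=float)
        wt = np.asarray(self.weight, dtype=float)
        if w_nm.size < 2:
            raise ValueError("tabulated spectrum needs at least two points")
        if np.any(np.diff(w_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(wt < 0):
            raise ValueError("weights must be non-negative")
        total = wt.sum()
        if total <= 0:
            raise ValueError("tabulated spectrum has zero total weight")
        object.__setattr__(self, "wavelength_nm", w_nm)
        object.__setattr__(self, "weight", wt / total)

    @classmethod
    def from_csv(cls, path) -> "TabulatedSpectrum":
        """Load a 2-column CSV with header ``wavelength_nm,intensity``."""
        df = pd.read_csv(path, comment="#")
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # histogram (inverse-CDF) sampling: each grid point carries its
        # tabulated mass, spread uniformly over the cell bounded by the
        # midpoints to its neighbours. A degenerate all-mass-at-one-
        # point table returns that point exactly.
        lam_grid, w = self.wavelength_nm, self.weight
        nz = np.flatnonzero(w)
        if nz.size == 1:
            return np.full(n, lam_grid[nz[0]])
        mids = (lam_grid[:-1] + lam_grid[1:]) / 2.0
        edges = np.concatenate([[lam_grid[0]], mids, [lam_grid[-1]]])
        cdf = np.cumsum(w)
        idx = np.searchsorted(cdf / cdf[-1], rng.random(n), side="right")
        idx = np.clip(idx, 0, lam_grid.size - 1)
        return rng.uniform(edges[idx], edges[idx + 1])


def sample_wavelengths(spectrum, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. photon wavelengths (nm) from an emission spectrum."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return spectrum.sample(int(n), rng)


# ---------------------------------------------------------------------------
# emitter and photon batch
# ---------------------------------------------------------------------------

@dataclass
class EmitterModel:
    """Ground-truth emitter: position, photon-count law, spectrum, PSF."""

    x0: float = 0.0
    y0: float = 0.0
    count_law: object = field(default_factory=lambda: FixedCount(700))
    spectrum: object = field(default_factory=lambda: GaussianSpectrum(680.0, 41.0))
    psf_sigma_coeff: float = PSF_SIGMA_COEFF
    na: float = NA_DEFAULT

    def __post_init__(self):
        if self.psf_sigma_coeff <= 0:
            raise ValueError("psf_sigma_coeff must be > 0")

    def psf_sigma(self, lam_nm):
        return psf_sigma(lam_nm, na=self.na, coeff=self.psf_sigma_coeff)


@dataclass
class PhotonBatch:
    """Per-photon state of one blinking event.

    ``theta`` (path labels) and ``xdisp`` are unset until the batch has
    passed the beamsplitter / dispersion stage of the optics module.
    """

    x: np.ndarray
    y: np.ndarray
    lam: np.ndarray
    theta: Optional[np.ndarray] = None
    xdisp: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.lam)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("photon vectors must have equal length")
        if n and (self.lam.min() < BAND_NM[0] or self.lam.max() > BAND_NM[1]):
            raise ValueError(f"wavelengths must lie within {BAND_NM}")

    def __len__(self) -> int:
        return len(self.lam)


def sample_psf_positions(x0: float, y0: float, sigma_psf, n: int,
                         rng: np.random.Generator):
    """Sample ``n`` photon positions from the Gaussian PSF around (x0, y0).

    ``sigma_psf`` may be a scalar or a per-photon array (wavelength-
    dependent PSF width).
    """
    sig = np.asarray(sigma_psf, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma_psf must be > 0")
    x = x0 + sig * rng.standard_normal(n)
    y = y0 + sig * rng.standard_normal(n)
    return x, y


def emit_photons(emitter: EmitterModel, rng: np.random.Generator,
                 n: Optional[int] = None) -> PhotonBatch:
    """Sample one full blinking event: count, wavelengths, positions."""
    if n is None:
        n = sample_photon_count(emitter.count_law, rng)
    lam = sample_wavelengths(emitter.spectrum, n, rng)
    sig = emitter.psf_sigma(lam)
    x, y = sample_psf_positions(emitter.x0, emitter.y0, sig, n, rng)
    return PhotonBatch(x=x, y=y, lam=lam)
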