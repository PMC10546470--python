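"""Beamsplitter routing, DWP spectral dispersion and calibration.

The dual-wedge-prism (DWP) module splits each photon into the
undispersed zeroth-order (spatial) path or the dispersed first-order
(spectral) path, or loses it. The wavelength-dependent lateral shift of
first-order photons follows an empirical rational function

    f(lam) = (8495*xi + 6132) / (xi**2 + 29.82*xi + 74.03),
    xi = (lam - 650) / 144.342,

valid from 400 to 900 nm and strictly increasing there. f is expressed
in arbitrary deflection units; the affine calibration

    xscaled = a * f(lam) + b

maps it to sensor pixels, and the closed-form inverse of f recovers the
wavelength of any calibrated pixel column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .photophysics import BAND_NM, PhotonBatch

# rational-function constants of the dispersion model
_P1, _P0 = 8495.0, 6132.0
_Q1, _Q0 = 29.82, 74.03
XI_CENTER = 650.0
XI_SCALE = 144.342

#: tolerated extrapolation (nm) past the valid band before erroring
BAND_CLAMP_NM = 5.0


class Path(IntEnum):
    """Photon path label after the beamsplitter."""
    LOST = -1
    ZEROTH = 0
    FIRST = 1


def _check_band(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    lo, hi = BAND_NM
    if np.any(lam < lo - BAND_CLAMP_NM) or np.any(lam > hi + BAND_CLAMP_NM):
        raise ValueError(f"wavelength outside valid band {BAND_NM} nm")
    return np.clip(lam, lo, hi)


def dispersion_f(lam):
    """Dispersion shift f(lam) in deflection units; valid on [400, 900] nm."""
    lam = _check_band(lam)
    xi = (lam - XI_CENTER) / XI_SCALE
    return (_P1 * xi + _P0) / (xi * xi + _Q1 * xi + _Q0)


def dispersion_f_prime(lam):
    """df/dlam in deflection units per nm (positive on the valid band)."""
    lam = _check_band(lam)
    xi = (lam - XI_CENTER) / XI_SCALE
    den = xi * xi + _Q1 * xi + _Q0
    num = _P1 * xi + _P0
    dxi = (_P1 * den - num * (2.0 * xi + _Q1)) / (den * den)
    return dxi / XI_SCALE


def inverse_f(xdisp):
    """Closed-form inverse of the dispersion function, returning nm.

    Solving x*xi^2 + (29.82*x - 8495)*xi + (74.03*x - 6132) = 0 for xi,
    the physical branch (the one inside the valid band) is the
    quadratic root that stays finite as x -> 0; it is evaluated in the
    cancellation-free form 2c / (-b + sqrt(b^2 - 4ac)).
    """
    x = np.asarray(xdisp, dtype=float)
    lo, hi = dispersion_f(BAND_NM[0]), dispersion_f(BAND_NM[1])
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("dispersion value outside the range of f on the band")
    b = _Q1 * x - _P1
    c = _Q0 * x - _P0
    disc = b * b - 4.0 * x * c
    xi = 2.0 * c / (-b + np.sqrt(disc))
    return XI_CENTER + XI_SCALE * xi


# ---------------------------------------------------------------------------
# calibration (dispersion units <-> sensor pixels)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Affine map xscaled = a*f(lam) + b from deflection units to pixels."""
    a: float
    b: float
    band_nm: tuple = BAND_NM

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("calibration scale a must be nonzero")

    def to_json(self, path, anchors=None):
        payload = {"a": self.a, "b": self.b, "band_nm": list(self.band_nm),
                   "anchors": anchors or []}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(a=d["a"], b=d["b"], band_nm=tuple(d.get("band_nm", BAND_NM)))


def apply_calibration(xdisp, calibration: Calibration):
    """Map dispersion units to sensor pixels: a*xdisp + b."""
    return calibration.a * np.asarray(xdisp, dtype=float) + calibration.b


def pixel_to_wavelength(xscaled, calibration: Calibration):
    """Invert the calibrated dispersion: lam = f^-1((xscaled - b)/a)."""
    return inverse_f((np.asarray(xscaled, dtype=float) - calibration.b)
                     / calibration.a)


def wavelength_to_pixel(lam, calibration: Calibration):
    """Pixel column of wavelength ``lam`` under a calibration."""
    return apply_calibration(dispersion_f(lam), calibration)


def dispersion_nm_per_px(lam, calibration: Calibration):
    """Local linear-equivalent dispersion |dlam/dx| in nm per pixel."""
    return 1.0 / (abs(calibration.a) * dispersion_f_prime(lam))


def default_calibration(nm_per_px_at_650: float = 4.3,
                        b: float = 0.0) -> Calibration:
    """Calibration anchored to the linear-equivalent dispersion at 650 nm.

    ``a`` is chosen so one pixel spans ``nm_per_px_at_650`` nanometres
    at 650 nm (the nominal 4.3 nm/px of the DWP).
    """
    a = (1.0 / nm_per_px_at_650) / dispersion_f_prime(650.0)
    return Calibration(a=a, b=b)


# ---------------------------------------------------------------------------
# efficiency (beamsplitter + prisms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NominalEfficiency:
    """Wavelength-independent splitting: R -> spatial, T -> spectral.

    The reflected arm of the beamsplitter feeds the zeroth-order
    (spatial) image via the right-angle prism; the transmitted arm is
    dispersed by the wedge prisms. ``loss_zeroth``/``loss_first`` model
    a flat excess loss on each arm (default lossless).
    """
    reflect: float = 0.5
    transmit: float = 0.5
    loss_zeroth: float = 0.0
    loss_first: float = 0.0

    def __post_init__(self):
        if not (0 <= self.reflect <= 1 and 0 <= self.transmit <= 1):
            raise ValueError("reflect/transmit must be in [0, 1]")
        if self.reflect + self.transmit > 1 + 1e-9:
            raise ValueError("reflect + transmit must not exceed 1")
        if not (0 <= self.loss_zeroth <= 1 and 0 <= self.loss_first <= 1):
            raise ValueError("loss fractions must be in [0, 1]")

    def probabilities(self, lam):
        lam = np.asarray(lam, dtype=float)
        p0 = np.full(lam.shape, self.reflect * (1.0 - self.loss_zeroth))
        p1 = np.full(lam.shape, self.transmit * (1.0 - self.loss_first))
        return p0, p1, 1.0 - p0 - p1


@dataclass(frozen=True)
class TabulatedEfficiency:
    """Measured per-wavelength splitting fractions, linearly interpolated.

    Wavelengths up to ``BAND_CLAMP_NM`` outside the tabulated support
    are clamped to the nearest endpoint; farther out is an error.
    """
    wavelength_nm: np.ndarray
    reflect: np.ndarray
    transmit: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelength_nm, dtype=float)
        r = np.asarray(self.reflect, dtype=float)
        t = np.asarray(self.transmit, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < 0) or np.any(t < 0) or np.any(r + t > 1 + 1e-6):
            raise ValueError("invalid efficiency fractions")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "reflect", r)
        object.__setattr__(self, "transmit", t)

    @classmethod
    def from_csv(cls, path) -> "TabulatedEfficiency":
        """Load ``wavelength_nm,reflect,transmit,loss`` (rows sum to 1)."""
        df = pd.read_csv(path, comment="#")
        total = df["reflect"] + df["transmit"] + df["loss"]
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise ValueError("efficiency rows must sum to 1")
        return cls(df["wavelength_nm"].to_numpy(), df["reflect"].to_numpy(),
                   df["transmit"].to_numpy())

    def probabilities(self, lam):
        lam = np.asarray(lam, dtype=float)
        w = self.wavelength_nm
        if np.any(lam < w[0] - BAND_CLAMP_NM) or np.any(lam > w[-1] + BAND_CLAMP_NM):
            raise ValueError("wavelength outside the efficiency table support")
        lam = np.clip(lam, w[0], w[-1])
        p0 = np.interp(lam, w, self.reflect)
        p1 = np.interp(lam, w, self.transmit)
        return p0, p1, 1.0 - p0 - p1


def split_photons(lam, efficiency, rng: np.random.Generator) -> np.ndarray:
    """Draw a path label per photon from the efficiency function."""
    lam = np.asarray(lam, dtype=float)
    p0, p1, _ = efficiency.probabilities(lam)
    u = rng.random(lam.shape)
    theta = np.where(u < p0, int(Path.ZEROTH),
                     np.where(u < p0 + p1, int(Path.FIRST), int(Path.LOST)))
    return theta.astype(np.int8)


# ---------------------------------------------------------------------------
# optical model and dispersal
# ---------------------------------------------------------------------------

@dataclass
class OpticalModel:
    """Efficiency + dispersion + calibration of the DWP module."""

    efficiency: object = field(default_factory=NominalEfficiency)
    calibration: Calibration = field(default_factory=default_calibration)
    zeroth_offset_px: float = 0.0
    valid_band: tuple = BAND_NM


def disperse(batch: PhotonBatch, model: OpticalModel,
             pixel_pitch_nm: float = 160.0) -> PhotonBatch:
    """Apply the dispersion stage: shift first-order photons along x.

    Zeroth-order photons keep their position plus the fixed channel
    offset separating the two image regions; first-order photons are
    shifted by the calibrated dispersion converted to object-space nm;
    lost photons are dropped. ``theta`` must already be assigned.
    """
    if batch.theta is None:
        raise RuntimeError("photon paths unassigned: run split_photons first")
    keep = batch.theta != int(Path.LOST)
    x, y, lam = batch.x[keep], batch.y[keep], batch.lam[keep]
    theta = batch.theta[keep]
    xdisp = np.zeros_like(x)
    first = theta == int(Path.FIRST)
    xdisp[first] = dispersion_f(lam[first])
    shift_px = np.where(first,
                        apply_calibration(xdisp, model.calibration),
                        model.zeroth_offset_px)
    return PhotonBatch(x=x + shift_px * pixel_pitch_nm, y=y, lam=lam,
                       theta=theta, xdisp=np.where(first, xdisp, np.nan))
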