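"""EMCCD frame rendering: pixelation, background, EM gain, readout.

Photon positions are binned onto the pixel grid (signal S), Poisson
background B is added per pixel, the electron-multiplying register is
modelled as a Gamma draw with shape S+B and scale equal to the EM gain
A, the result is converted to ADU by the analog-to-digital unit U, and
Gaussian readout noise is added:

    Z = Gamma(S + B, A)/U + R,   R ~ Normal(0, bro) * A/U

The readout term scaled by A/U makes 1.9 e- of readout noise act as
1.9 photon-equivalents per pixel after gain normalization; the more
conventional post-gain placement (R/U only) is available through
``readout_convention="post_gain"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

try:  # optional at runtime: only needed for TIFF export
    import tifffile
except ImportError:  # pragma: no cover
    tifffile = None


@dataclass
class DetectorModel:
    """EMCCD geometry and noise constants (object-space units)."""

    ax: float = 160.0      # pixel pitch along x, nm/px (16 um / 100x)
    ay: float = 160.0      # pixel pitch along y, nm/px
    em_gain: float = 100.0  # A: electrons out per photoelectron
    adu: float = 13.6       # U: electrons per ADU count
    bro: float = 1.9        # readout-noise sd, e-
    bbg: float = 15.0       # mean background photons per pixel
    shape: tuple = (64, 256)  # sensor rows x cols
    readout_convention: str = "table1"   # "table1" | "post_gain"
    quantize: bool = False

    def __post_init__(self):
        if min(self.ax, self.ay, self.em_gain, self.adu) <= 0:
            raise ValueError("ax, ay, em_gain and adu must be positive")
        if self.bro < 0 or self.bbg < 0:
            raise ValueError("bro and bbg must be non-negative")
        if self.readout_convention not in ("table1", "post_gain"):
            raise ValueError("readout_convention must be 'table1' or 'post_gain'")

    @property
    def adu_per_photon(self) -> float:
        """Mean ADU counts produced by one photoelectron (A/U)."""
        return self.em_gain / self.adu


@dataclass
class Frame:
    """A rendered pixel array in ADU plus optional ground-truth record."""

    Z: np.ndarray
    truth: Optional[dict] = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("frame contains non-finite pixels")


def accumulate(x_nm, y_nm, detector: DetectorModel,
               shape: Optional[tuple] = None,
               origin_nm: tuple = (0.0, 0.0)):
    """Bin photon positions into an integer signal array S.

    Bins are half-open ``[lo, hi)`` intervals of width (ay, ax) nm
    starting at ``origin_nm`` (row, col); a photon exactly on a shared
    edge therefore lands in the higher-index pixel. Photons outside the
    array are dropped and counted.

    Returns ``(S, n_dropped)`` with ``S[row, col]`` ordering.
    """
    shape = detector.shape if shape is None else shape
    rows = np.floor((np.asarray(y_nm, dtype=float) - origin_nm[0])
                    / detector.ay).astype(np.int64)
    cols = np.floor((np.asarray(x_nm, dtype=float) - origin_nm[1])
                    / detector.ax).astype(np.int64)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    S = np.zeros(shape, dtype=np.int64)
    np.add.at(S, (rows[ok], cols[ok]), 1)
    return S, int((~ok).sum())


def read_out(S, detector: DetectorModel, rng: np.random.Generator,
             truth: Optional[dict] = None) -> Frame:
    """Render the EMCCD output Z (ADU) from an integer signal array."""
    S = np.asarray(S)
    if np.any(S < 0):
        raise ValueError("signal array must be non-negative")
    B = rng.poisson(detector.bbg, size=S.shape) if detector.bbg > 0 else 0
    k = S + B
    amplified = np.zeros(S.shape, dtype=float)
    pos = k > 0
    # Gamma(shape k, scale A); shape 0 contributes exactly 0 electrons
    amplified[pos] = rng.gamma(k[pos], detector.em_gain)
    Z = amplified / detector.adu
    if detector.bro > 0:
        scale = (detector.adu_per_photon if detector.readout_convention == "table1"
                 else 1.0 / detector.adu)
        Z = Z + rng.normal(0.0, detector.bro, size=S.shape) * scale
    if detector.quantize:
        Z = np.round(Z)
    return Frame(Z=Z, truth=truth)


def subtract_background(frame: Frame, detector: DetectorModel) -> np.ndarray:
    """Z' = Z - (A/U)*bbg: remove the mean background level in ADU."""
    return frame.Z - detector.adu_per_photon * detector.bbg


def gain_normalize(z_adu, detector: DetectorModel) -> np.ndarray:
    """Convert ADU to photon-equivalent electrons: e = Z * U / A."""
    return np.asarray(z_adu, dtype=float) / detector.adu_per_photon


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------

def write_frames(path, frames, sidecar: bool = True) -> None:
    """Write frames as a multi-page 32-bit float TIFF (+ JSON truth sidecar)."""
    if tifffile is None:  # pragma: no cover
        raise RuntimeError("tifffile is required for TIFF export")
    stack = np.stack([f.Z.astype(np.float32) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    if sidecar:
        meta = [f.truth if f.truth is not None else {} for f in frames]
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1, default=float)


def read_frames(path):
    """Read a TIFF stack written by :func:`write_frames`."""
    if tifffile is None:  # pragma: no cover
        raise RuntimeError("tifffile is required for TIFF import")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = [None] * len(stack)
    return [Frame(Z=z.astype(float), truth=m) for z, m in zip(stack, meta)]
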