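"""End-to-end simulation runs: single events, sweeps and comparisons.

Two simulation modes are provided:

* ``theory`` (theory-validation): all photons are routed into the
  analyzed channel and the spectral channel uses a uniform linear
  dispersion (nm/px). This matches the assumptions behind the
  closed-form precision equations and is the mode used to benchmark
  the Monte Carlo engine against them.
* ``dwp``: the full system — wavelength-dependent beamsplitting into
  zeroth/first order, the nonlinear rational dispersion with its
  affine pixel calibration, and both channels rendered and analyzed
  (the spatial localization provides the wavelength reference for the
  spectral window).

Each repeat is an independent blinking event with its own subpixel
emitter placement; precisions are standard deviations of the estimate
minus the per-repeat truth. Seeding uses one master seed and spawned,
order-independent child streams per repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path as FsPath
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import optics, photophysics, theory
from .analysis import (SpectralWindow, estimate_precision, mle_localize,
                       spectral_centroid, fit_spectrum,
                       extract_spectral_window)
from .detector import DetectorModel, read_out, accumulate
from .optics import (NominalEfficiency, Calibration, default_calibration,
                     dispersion_f, inverse_f, split_photons, Path)
from .photophysics import (EmitterModel, FixedCount, GaussianSpectrum,
                           LognormalCount, emit_photons, psf_sigma)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation configuration mirroring the system's standard constants."""

    # emitter
    n_photons: int = 700
    count_law: str = "fixed"          # "fixed" | "lognormal"
    mu_log: float = float(np.log(700.0))
    sigma_log: float = 0.7
    peak_nm: float = 680.0
    fwhm_nm: float = 41.0
    psf_coeff: float = photophysics.PSF_SIGMA_COEFF
    na: float = 1.49
    # detector
    bbg: float = 15.0
    bro: float = 1.9
    em_gain: float = 100.0
    adu: float = 13.6
    ax_nm: float = 160.0
    ay_nm: float = 160.0
    fem: float = 2.0
    # spectral channel
    a_lambda: float = 5.0             # linear dispersion, nm/px (theory mode)
    nm_per_px_at_650: float = 4.3     # DWP linear-equivalent anchor
    spectral_band: tuple = (450.0, 800.0)
    row_halfwidth: int = 3            # spectral window y half-extent, px
    negative_weights: str = "clip"    # centroid handling of negatives
    # wavelength-axis anchoring: the spectral window is cut at integer
    # pixel columns relative to the zeroth-order image, so by default the
    # axis is referenced at pixel resolution (the subpixel remainder of
    # the reference position is unmodelled, giving the a_lambda^2/12
    # spectral-discretization variance floor). "subpixel" removes it.
    axis_reference: str = "pixel"     # "pixel" | "subpixel"
    # spatial channel
    roi: int = 15                     # spatial ROI side, px
    subpixel: bool = True             # random subpixel emitter placement
    # beamsplitter (dwp mode): reflected arm feeds the spatial channel
    bs_reflect: float = 0.5
    bs_transmit: float = 0.5
    excess_loss: float = 0.0
    # DWP sweeps quote the photon budget as the spatial-channel count of
    # the reference R50:T50 splitter, so the emitted count per event is
    # n_photons / bs_reference_reflect for every splitter under test
    # (the same source compared through different splitters).
    bs_reference_reflect: float = 0.5

    def detector_model(self, shape=None) -> DetectorModel:
        return DetectorModel(ax=self.ax_nm, ay=self.ay_nm, em_gain=self.em_gain,
                             adu=self.adu, bro=self.bro, bbg=self.bbg,
                             shape=shape or (64, 256))

    def emitter(self, n: Optional[int] = None) -> EmitterModel:
        law = FixedCount(n if n is not None else self.n_photons) \
            if self.count_law == "fixed" \
            else LognormalCount(self.mu_log, self.sigma_log)
        return EmitterModel(count_law=law,
                            spectrum=GaussianSpectrum(self.peak_nm, self.fwhm_nm),
                            psf_sigma_coeff=self.psf_coeff, na=self.na)

    def efficiency(self) -> NominalEfficiency:
        return NominalEfficiency(reflect=self.bs_reflect,
                                 transmit=self.bs_transmit,
                                 loss_zeroth=self.excess_loss,
                                 loss_first=self.excess_loss)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["spectral_band"] = list(self.spectral_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["spectral_band"] = tuple(d.get("spectral_band", (450.0, 800.0)))
        return cls(**d)


def child_rngs(seed: int, stream: int, n: int):
    """Order-independent per-repeat generators from one master seed."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# single-event simulators
# ---------------------------------------------------------------------------

def simulate_spatial_event(cfg: SimConfig, rng: np.random.Generator,
                           n_photons: Optional[int] = None,
                           positions=None, return_frame: bool = False):
    """Render one spatial-channel ROI and localize it.

    Returns ``(LocalizationResult, truth_x_nm, truth_y_nm)`` with truth
    and estimate both relative to the ROI origin; with ``return_frame``
    the rendered :class:`~dwpsim.detector.Frame` (truth metadata
    attached) is appended to the tuple.
    """
    det = cfg.detector_model()
    roi = cfg.roi
    u = rng.uniform(-0.5, 0.5, size=2) if cfg.subpixel else np.zeros(2)
    x0 = (roi / 2.0 + u[0]) * det.ax
    y0 = (roi / 2.0 + u[1]) * det.ay
    if positions is None:
        emitter = replace_position(cfg.emitter(n_photons), x0, y0)
        batch = emit_photons(emitter, rng)
        x, y = batch.x, batch.y
    else:
        x, y = positions[0] + x0, positions[1] + y0
    S, _ = accumulate(x, y, det, shape=(roi, roi))
    frame = read_out(S, det, rng,
                     truth={"x_true_nm": x0, "y_true_nm": y0,
                            "n_photons": len(x)} if return_frame else None)
    loc = mle_localize(frame.Z, det)
    if return_frame:
        return loc, x0, y0, frame
    return loc, x0, y0


def replace_position(emitter: EmitterModel, x0: float, y0: float) -> EmitterModel:
    emitter.x0, emitter.y0 = x0, y0
    return emitter


def simulate_spectral_event_linear(cfg: SimConfig, rng: np.random.Generator,
                                   n_photons: Optional[int] = None,
                                   estimators: Sequence[str] = ("centroid",)):
    """One spectral-channel event under uniform linear dispersion.

    All photons land in the spectral window (theory-validation mode);
    the wavelength reference is the true emitter position. Returns a
    dict of SpectralResult keyed by estimator plus the true peak.
    """
    det = cfg.detector_model()
    lo, hi = cfg.spectral_band
    ncols = int(round((hi - lo) / cfg.a_lambda))
    nrows = 2 * cfg.row_halfwidth + 1
    u = rng.uniform(-0.5, 0.5, size=2) if cfg.subpixel else np.zeros(2)

    emitter = cfg.emitter(n_photons)
    batch = emit_photons(emitter, rng)
    col_nm = (batch.lam - lo) / cfg.a_lambda * det.ax + (batch.x + u[0] * det.ax)
    row_nm = batch.y + (nrows / 2.0 + u[1]) * det.ay
    S, _ = accumulate(col_nm, row_nm, det, shape=(nrows, ncols))
    frame = read_out(S, det, rng)

    ref = 0.0 if cfg.axis_reference == "pixel" else u[0]

    def lam_of_col(col):
        return lo + (np.asarray(col, dtype=float) - ref) * cfg.a_lambda

    window = extract_spectral_window(frame.Z, det, lam_of_col,
                                     band=cfg.spectral_band,
                                     row_halfwidth=cfg.row_halfwidth)
    out = {}
    for est in estimators:
        out[est] = _run_estimator(window, est, cfg)
    return out, cfg.peak_nm


def _run_estimator(window: SpectralWindow, est: str, cfg: SimConfig):
    if est == "centroid":
        return spectral_centroid(window, negative_weights=cfg.negative_weights)
    if est == "fit1d":
        return fit_spectrum(window, mode="FIT_1D")
    if est == "fit2d":
        return fit_spectrum(window, mode="FIT_2D")
    raise ValueError(f"unknown estimator {est!r}")


def simulate_dwp_event(cfg: SimConfig, rng: np.random.Generator,
                       n_photons: Optional[int] = None,
                       estimators: Sequence[str] = ("fit2d",),
                       calibration: Optional[Calibration] = None):
    """One full DWP event: split, disperse, render and analyze both ROIs.

    Returns ``(loc_error_nm or nan, {estimator: mu_error_nm or nan})``.
    The spectral wavelength axis is referenced to the *estimated*
    zeroth-order position, as in the real pipeline.
    """
    det = cfg.detector_model()
    calib = calibration or default_calibration(cfg.nm_per_px_at_650)
    lo, hi = cfg.spectral_band
    f_lo, f_hi = dispersion_f(lo), dispersion_f(hi)
    pad = 4
    ncols = int(np.ceil(calib.a * (f_hi - f_lo))) + 2 * pad
    nrows = 2 * cfg.row_halfwidth + 1
    roi = cfg.roi
    u = rng.uniform(-0.5, 0.5, size=2) if cfg.subpixel else np.zeros(2)

    n_nominal = cfg.n_photons if n_photons is None else n_photons
    n_emitted = int(round(n_nominal / cfg.bs_reference_reflect))
    emitter = cfg.emitter(n_emitted)
    batch = emit_photons(emitter, rng)
    theta = split_photons(batch.lam, cfg.efficiency(), rng)

    # ---- spatial channel (zeroth order: reflected arm)
    zer = theta == int(Path.ZEROTH)
    x0 = (roi / 2.0 + u[0]) * det.ax
    y0 = (roi / 2.0 + u[1]) * det.ay
    Ssp, _ = accumulate(batch.x[zer] + x0, batch.y[zer] + y0, det,
                        shape=(roi, roi))
    loc_err = np.nan
    delta_px = 0.0
    loc_ok = False
    try:
        loc = mle_localize(read_out(Ssp, det, rng).Z, det)
        # quality gate: reject estimates that wandered off the centred
        # emitter (failed fits on photon-starved frames)
        central = (abs(loc.x_hat - x0) < roi / 8 * det.ax
                   and abs(loc.y_hat - y0) < roi / 8 * det.ay)
        loc_ok = loc.converged and central
        loc_err = loc.x_hat - x0
        delta_px = loc_err / det.ax
    except ValueError:
        pass

    # ---- spectral channel (first order: transmitted arm)
    fir = theta == int(Path.FIRST)
    lamf = batch.lam[fir]
    col_px = calib.a * (dispersion_f(lamf) - f_lo) + pad \
        + (batch.x[fir] / det.ax + u[0])
    row_nm = batch.y[fir] + (nrows / 2.0 + u[1]) * det.ay
    Ssl, _ = accumulate(col_px * det.ax, row_nm, det, shape=(nrows, ncols))
    frame = read_out(Ssl, det, rng)

    ref_px = u[0] + (delta_px if loc_ok else 0.0)
    if cfg.axis_reference == "pixel":
        ref_px = float(np.round(ref_px))

    def lam_of_col(col):
        xscaled = (np.asarray(col, dtype=float) - pad - ref_px) / calib.a + f_lo
        return inverse_f(np.clip(xscaled, dispersion_f(400.0),
                                 dispersion_f(900.0)))

    spec_err = {}
    try:
        window = extract_spectral_window(frame.Z, det, lam_of_col,
                                         band=cfg.spectral_band,
                                         row_halfwidth=cfg.row_halfwidth)
        for est in estimators:
            try:
                r = _run_estimator(window, est, cfg)
                spec_err[est] = (r.mu_hat - cfg.peak_nm) if r.converged else np.nan
            except ValueError:
                spec_err[est] = np.nan
    except ValueError:
        for est in estimators:
            spec_err[est] = np.nan
    return (loc_err if loc_ok else np.nan), spec_err


# ---------------------------------------------------------------------------
# condition runners
# ---------------------------------------------------------------------------

def run_localization_repeats(cfg: SimConfig, repeats: int, seed: int,
                             stream: int = 0):
    """Theory-mode localization precision at one condition."""
    errors = np.empty(repeats)
    ok = np.zeros(repeats, dtype=bool)
    for i, rng in enumerate(child_rngs(seed, stream, repeats)):
        loc, x0, _ = simulate_spatial_event(cfg, rng)
        errors[i] = loc.x_hat - x0
        ok[i] = loc.converged
    return estimate_precision(errors, 0.0, converged=ok)


def run_spectral_repeats(cfg: SimConfig, repeats: int, seed: int,
                         estimators: Sequence[str] = ("centroid",),
                         stream: int = 1):
    """Theory-mode spectral precision at one condition, per estimator."""
    errs = {est: np.full(repeats, np.nan) for est in estimators}
    for i, rng in enumerate(child_rngs(seed, stream, repeats)):
        results, mu_true = simulate_spectral_event_linear(
            cfg, rng, estimators=estimators)
        for est, r in results.items():
            if r.converged:
                errs[est][i] = r.mu_hat - mu_true
    return {est: estimate_precision(v, 0.0) for est, v in errs.items()}


def run_dwp_repeats(cfg: SimConfig, repeats: int, seed: int,
                    estimators: Sequence[str] = ("fit2d",), stream: int = 2):
    """Full-DWP precisions (localization + spectral) at one condition."""
    loc_err = np.full(repeats, np.nan)
    spec = {est: np.full(repeats, np.nan) for est in estimators}
    calib = default_calibration(cfg.nm_per_px_at_650)
    for i, rng in enumerate(child_rngs(seed, stream, repeats)):
        le, se = simulate_dwp_event(cfg, rng, estimators=estimators,
                                    calibration=calib)
        loc_err[i] = le
        for est in estimators:
            spec[est][i] = se[est]
    out = {"loc": estimate_precision(loc_err, 0.0)}
    for est in estimators:
        out[est] = estimate_precision(spec[est], 0.0)
    return out


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

SWEEP_PARAMS = {
    "photons": "n_photons",
    "background": "bbg",
    "peak": "peak_nm",
    "fwhm": "fwhm_nm",
}


@dataclass
class SweepSpec:
    """A one-parameter sweep at otherwise fixed conditions."""

    param: str                      # photons | background | peak | fwhm
    grid: Sequence[float]
    base: SimConfig = field(default_factory=SimConfig)
    mode: str = "theory"            # "theory" | "dwp"
    repeats: int = 1000
    seed: int = 0
    estimators: tuple = ("centroid", "fit2d")

    def __post_init__(self):
        if self.param not in SWEEP_PARAMS:
            raise ValueError(f"unknown sweep parameter {self.param!r}")
        if len(self.grid) == 0:
            raise ValueError("sweep grid must be non-empty")
        if self.repeats < 100:
            raise ValueError("repeats must be >= 100")


def _condition(base: SimConfig, param: str, value) -> SimConfig:
    kwargs = asdict(base)
    kwargs["spectral_band"] = base.spectral_band
    kwargs[SWEEP_PARAMS[param]] = int(value) if param == "photons" else float(value)
    return SimConfig(**kwargs)


def _theory_overlays(cfg: SimConfig):
    sig = psf_sigma(cfg.peak_nm, na=cfg.na, coeff=cfg.psf_coeff)
    tp = theory.TheoryParams(sigma_x=sig, sigma_y=sig,
                             sigma_lam_fwhm=cfg.fwhm_nm, ax=cfg.ax_nm,
                             ay=cfg.ay_nm, a_lam=cfg.a_lambda,
                             n_photons=cfg.n_photons, bbg=cfg.bbg,
                             bro=cfg.bro, fem=cfg.fem)
    return (float(theory.localization_precision(tp)),
            float(theory.spectral_precision(tp)))


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run a sweep and tabulate Monte Carlo and theory precisions.

    Each grid point simulates ``spec.repeats`` independent events per
    analyzed channel. In theory mode the localization and spectral
    channels are simulated separately with all photons routed to each
    (matching the closed-form equations' assumptions); in dwp mode one
    shared event feeds both channels through the beamsplitter.
    """
    rows = []
    for gi, value in enumerate(spec.grid):
        cfg = _condition(spec.base, spec.param, value)
        th_loc, th_spec = _theory_overlays(cfg)
        row = {"param": spec.param, "value": float(value),
               "n_photons": cfg.n_photons, "bbg": cfg.bbg,
               "peak_nm": cfg.peak_nm, "fwhm_nm": cfg.fwhm_nm,
               "repeats": spec.repeats, "theory_loc": th_loc,
               "theory_spec_centroid": th_spec}
        if spec.mode == "theory":
            loc = run_localization_repeats(cfg, spec.repeats, spec.seed,
                                           stream=100 + gi)
            row["loc_precision"] = loc.precision
            row["loc_convergence"] = loc.convergence_rate
            specres = run_spectral_repeats(cfg, spec.repeats, spec.seed,
                                           estimators=spec.estimators,
                                           stream=200 + gi)
            for est, pe in specres.items():
                row[f"{est}_precision"] = pe.precision
                row[f"{est}_convergence"] = pe.convergence_rate
        elif spec.mode == "dwp":
            res = run_dwp_repeats(cfg, spec.repeats, spec.seed,
                                  estimators=spec.estimators, stream=300 + gi)
            row["loc_precision"] = res["loc"].precision
            row["loc_convergence"] = res["loc"].convergence_rate
            for est in spec.estimators:
                row[f"{est}_precision"] = res[est].precision
                row[f"{est}_convergence"] = res[est].convergence_rate
        else:
            raise ValueError(f"unknown mode {spec.mode!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def mc_theory_mae(sweep_result: pd.DataFrame, estimator: str = "loc") -> float:
    """Mean |MC - theory| (nm) over the grid for one estimator."""
    mc_col = f"{estimator}_precision"
    th_col = "theory_loc" if estimator == "loc" else "theory_spec_centroid"
    if mc_col not in sweep_result or th_col not in sweep_result:
        raise ValueError(f"sweep result lacks columns for {estimator!r}")
    return float(np.mean(np.abs(sweep_result[mc_col] - sweep_result[th_col])))


# ---------------------------------------------------------------------------
# beamsplitter comparison
# ---------------------------------------------------------------------------

#: Default sweep grids for the beamsplitter trade-off study, spanning
#: the stated ranges of the four system sweeps.
BS_SWEEP_GRIDS = {
    "photons": tuple(np.unique(np.round(np.geomspace(320, 5000, 6)).astype(int))),
    "background": (0.0, 10.0, 20.0, 30.0, 40.0, 50.0),
    "peak": (500.0, 550.0, 600.0, 650.0, 700.0, 750.0),
    "fwhm": (10.0, 24.0, 38.0, 52.0, 66.0, 80.0),
}


def compare_beamsplitters(base: SimConfig = None, repeats: int = 600,
                          seed: int = 0, estimator: str = "fit2d",
                          grids: dict = None,
                          ratios=((0.5, 0.5), (0.3, 0.7))) -> pd.DataFrame:
    """Matched DWP sweeps for two beamsplitter ratios.

    Runs the four sweeps (photon count, background, spectral peak,
    spectral FWHM) for each R:T ratio with identical grids and seeds,
    and tabulates the per-point percentage change from the first to the
    second ratio (positive localization change = worse precision;
    positive spectral change = worse precision).
    """
    base = base or SimConfig()
    grids = grids or BS_SWEEP_GRIDS
    frames = []
    for r, t in ratios:
        cfg_kwargs = asdict(base)
        cfg_kwargs["spectral_band"] = base.spectral_band
        cfg_kwargs.update(bs_reflect=r, bs_transmit=t)
        cfg = SimConfig(**cfg_kwargs)
        for param, grid in grids.items():
            sw = SweepSpec(param=param, grid=grid, base=cfg, mode="dwp",
                           repeats=repeats, seed=seed,
                           estimators=(estimator,))
            df = run_sweep(sw)
            df["bs"] = f"R{int(r*100)}:T{int(t*100)}"
            frames.append(df)
    all_df = pd.concat(frames, ignore_index=True)
    first, second = [f"R{int(r*100)}:T{int(t*100)}" for r, t in ratios]
    a = all_df[all_df.bs == first].set_index(["param", "value"])
    b = all_df[all_df.bs == second].set_index(["param", "value"])
    if not a.index.equals(b.index):
        raise ValueError("mismatched sweep grids between beamsplitter configs")
    out = pd.DataFrame({
        "loc_a": a["loc_precision"], "loc_b": b["loc_precision"],
        "spec_a": a[f"{estimator}_precision"],
        "spec_b": b[f"{estimator}_precision"]})
    out["loc_change_pct"] = 100.0 * (out.loc_b / out.loc_a - 1.0)
    out["spec_change_pct"] = 100.0 * (out.spec_b / out.spec_a - 1.0)
    return out.reset_index()


# ---------------------------------------------------------------------------
# simulated spectral calibration
# ---------------------------------------------------------------------------

DEFAULT_BANDPASS_CENTRES = (532.0, 605.0, 635.0, 685.0, 750.0)


def simulate_calibration(true_calibration: Calibration,
                         rng: np.random.Generator,
                         bandpass_centres=DEFAULT_BANDPASS_CENTRES,
                         n_photons: int = 5000,
                         cfg: SimConfig = None):
    """Recover (a, b) from simulated narrowband calibration images.

    Point sources behind each bandpass filter are dispersed through the
    first-order path; the mean measured column per filter is regressed
    linearly on f(lambda_c) to fit the affine calibration.

    Returns ``(Calibration, residuals_px)``.
    """
    centres = np.asarray(bandpass_centres, dtype=float)
    if centres.size < 2 or np.unique(centres).size < 2:
        raise ValueError("need at least two distinct bandpass centres")
    cfg = cfg or SimConfig()
    det = cfg.detector_model()
    measured = np.empty(centres.size)
    for i, lam_c in enumerate(centres):
        true_px = optics.wavelength_to_pixel(lam_c, true_calibration)
        sigma = psf_sigma(lam_c, na=cfg.na, coeff=cfg.psf_coeff) / det.ax
        if n_photons > 0:
            cols = true_px + sigma * rng.standard_normal(n_photons)
            measured[i] = float(cols.mean())
        else:
            measured[i] = float(true_px)
    fvals = dispersion_f(centres)
    A = np.vstack([fvals, np.ones_like(fvals)]).T
    (a_fit, b_fit), *_ = np.linalg.lstsq(A, measured, rcond=None)
    resid = measured - (a_fit * fvals + b_fit)
    return Calibration(a=float(a_fit), b=float(b_fit)), resid


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("af647_like_spectrum", "gaussian_spectrum",
                 "nominal_bs_50_50", "nominal_bs_30_70", "default_config")


def make_fixture(kind: str, out_dir, peak_nm: float = 680.0,
                 fwhm_nm: float = 41.0) -> FsPath:
    """Write a deterministic fixture file and return its path.

    ``af647_like_spectrum`` is a synthetic stand-in for a measured
    AF647 emission spectrum: a main band near 668 nm with a red
    vibronic shoulder. It is illustrative, not a measured curve.
    """
    out_dir = FsPath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "af647_like_spectrum":
        lam = np.arange(600.0, 851.0, 1.0)
        main = np.exp(-0.5 * ((lam - 668.0) / 17.0) ** 2)
        shoulder = 0.35 * np.exp(-0.5 * ((lam - 720.0) / 28.0) ** 2)
        w = main + shoulder
        df = pd.DataFrame({"wavelength_nm": lam, "intensity": w / w.sum()})
        path = out_dir / "af647_like_spectrum.csv"
        _write_csv(path, df, "synthetic AF647-like emission spectrum (illustrative)")
    elif kind == "gaussian_spectrum":
        sd = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        lam = np.arange(np.floor(peak_nm - 6 * sd), np.ceil(peak_nm + 6 * sd) + 1)
        w = np.exp(-0.5 * ((lam - peak_nm) / sd) ** 2)
        df = pd.DataFrame({"wavelength_nm": lam, "intensity": w / w.sum()})
        path = out_dir / f"gaussian_spectrum_{int(peak_nm)}_{int(fwhm_nm)}.csv"
        _write_csv(path, df, f"gaussian spectrum peak={peak_nm} fwhm={fwhm_nm}")
    elif kind in ("nominal_bs_50_50", "nominal_bs_30_70"):
        r = 0.5 if kind.endswith("50_50") else 0.3
        lam = np.arange(400.0, 901.0, 25.0)
        df = pd.DataFrame({"wavelength_nm": lam,
                           "reflect": np.full(lam.size, r),
                           "transmit": np.full(lam.size, 1.0 - r),
                           "loss": np.zeros(lam.size)})
        path = out_dir / f"{kind}.csv"
        _write_csv(path, df, f"nominal lossless beamsplitter R{int(r*100)}")
    elif kind == "default_config":
        path = out_dir / "default_config.yaml"
        SimConfig().to_yaml(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    return path


def _write_csv(path, df: pd.DataFrame, note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dwpsim fixture: {note}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_sweep_csv(df: pd.DataFrame, path, seed: int,
                    config: SimConfig = None) -> None:
    """Write a sweep table with a reproducibility metadata header."""
    import hashlib
    cfg = config or SimConfig()
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# dwpsim sweep; seed={seed}; config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=False, float_format="%.8g")
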