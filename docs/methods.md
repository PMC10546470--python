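# Methods

## Model overview

`dwpsim` simulates one photoswitching (blinking) event at a time. An
event emits N photons in a single frame; each photon carries a
wavelength λ drawn from the emission spectrum and a lateral position
drawn from a 2D Gaussian PSF centred on the emitter. Photons then pass
a beamsplitter: with probability R(λ) they form the zeroth-order
(spatial) image, with probability T(λ) they enter the first-order
(spectral) path and are shifted along x by the dual-wedge-prism
dispersion, and otherwise they are lost. Both images land on one EMCCD,
whose output per pixel is

    Z = Γ(S + B, A) / U + R,

with S the photon count in the pixel, B ~ Poisson(b_bg) the background,
Γ(k, A) the electron-multiplying register (Gamma with integer shape k
and scale equal to the EM gain A; shape 0 yields exactly 0), U the
analog-to-digital conversion and R ~ Normal(0, b_ro)·A/U the readout
noise. Background subtraction is Z′ = Z − (A/U)·b_bg with the known
mean level. Repeating the event many times and taking the standard
deviation of the estimated position x̂ (or spectral peak μ̂λ) against
the per-repeat ground truth gives the localization (spectral)
precision.

### Readout-noise convention

Scaling R by A/U makes 1.9 e⁻ of readout noise act as 1.9
photon-equivalents per pixel after gain normalization. This matches the
closed-form bounds used for validation, which add b_ro² directly to
b_bg in the background correction factor. The physically more common
post-gain placement (R/U, making readout negligible at gain 100) is
available as `readout_convention="post_gain"`; all defaults use the
former.

## Default parameters

| symbol | meaning | default |
|---|---|---|
| N | photons per event | 700 (fixed), or lognormal |
| b_bg | background photons / pixel | 15 |
| b_ro | readout noise sd | 1.9 e⁻ |
| A | EM gain | 100 |
| U | e⁻ per ADU | 13.6 |
| ax, ay | object-space pixel size | 160 nm (16 µm / 100×) |
| aλ | linear spectral dispersion (theory mode) | 5 nm/px |
| NA | numerical aperture | 1.49 |
| FEM | EMCCD excess-noise variance factor | 2 |
| peak / FWHM | Gaussian emission spectrum | 680 / 41 nm |
| k | PSF width coefficient, σ_psf = k·λ/NA | 0.35 |

The PSF width law is a modelling choice (no single convention exists
for the Gaussian-approximated Airy disc): k = 0.35 gives σ_psf ≈ 160 nm
(one pixel) at 680 nm, and with it the localization bound reproduces
the expected background-sweep endpoints (10.5 and 15.0 nm at N = 700,
b_bg = 0 and 30) to ~1%. The lognormal photon-count fixture
(μ_log = ln 700, σ_log = 0.7) is illustrative of a far-red dye at short
exposure, not a measured fit.

## Dispersion model and calibration

The DWP's wavelength-dependent shift is the empirical rational function

    f(λ) = (8495 ξ + 6132) / (ξ² + 29.82 ξ + 74.03),  ξ = (λ−650)/144.342,

strictly increasing and used from 400 to 900 nm. Its inverse is closed
form (the quadratic root that stays finite as f → 0, evaluated in the
cancellation-free form 2c/(−b+√(b²−4ac))). f is in arbitrary deflection
units; all physical meaning enters through the affine calibration
x_scaled = a·f(λ) + b. The default calibration anchors the
linear-equivalent dispersion to 4.3 nm/px at 650 nm; the local
dispersion then varies from ~0.9 nm/px at 450 nm to ~9.3 nm/px at
800 nm. A simulated calibration routine images narrowband point sources
(bandpass centres 532, 605, 635, 685, 750 nm) through the first-order
path and regresses measured column on f(λ_c) to recover (a, b).

Because the dispersion density varies across the band, a spectrally
uniform source renders non-uniformly on the sensor (brighter where more
nanometres map into one pixel, i.e. toward the red). Before
least-squares fitting, each spectral column is divided by its local
nm-per-pixel span; without this correction a Gaussian fit is biased
toward longer wavelengths. The intensity-weighted centroid is invariant
to this correction (each detected photon is one sample of λ), so it is
computed directly from per-column counts.

## Estimators

**Localization.** The spatial ROI (15×15 px) is gain-normalized
(e = Z·U/A) and fitted by maximum likelihood with a pixel-integrated 2D
Gaussian plus flat background, five parameters (x, y, σ, N, b),
Poisson log-likelihood, analytic gradients, L-BFGS-B (bounded, gradient
tolerance 1e-8, ≤200 iterations), moment-based initialization. Two
approximations are deliberate: (i) treating gain-normalized EMCCD data
as Poisson ignores the Gamma mixing — this inflates the estimator
variance by exactly the excess-noise factor FEM = 2 that the theory
bound applies; (ii) the Gaussian readout noise is folded in by adding
its photon-equivalent variance b_ro² to both data and model (the usual
noise-corrected Poisson device), without which readout-dominated frames
(b_bg ≈ 0) produce negative pixels that push the likelihood to −∞.

**Spectral window.** Columns whose calibrated wavelength lies in
450–800 nm and rows within ±3 px of the emitter row form the window.
The wavelength axis is referenced to the zeroth-order localization *at
integer-pixel resolution* — the window is cut on the pixel grid — so
the unmodelled subpixel remainder contributes the aλ²/12
spectral-discretization variance floor that also appears in the
closed-form bound. `axis_reference="subpixel"` removes this floor for
idealized studies. In theory-validation mode (all photons to one
channel, uniform dispersion) the true emitter position is the
reference; in DWP mode it is the MLE position.

**Spectral centroid.** μ̂λ = Σ wᵢλᵢ / Σ wᵢ over the
background-subtracted 1D profile, with negative weights clipped at zero
(configurable `keep`). Clipping adds a deterministic pull toward the
window mean but sharply reduces variance at high background.

**Spectral fitting.** Least-squares Gaussian + constant offset, either
on the y-summed profile (FIT_1D) or the full 2D subimage (FIT_2D:
amplitude, μλ, σλ, y-centre, σy, offset). Initialization uses a
noise-normalized matched filter (Gaussian kernel, σ = 15 nm, response
divided by its per-position noise norm so that strongly dispersed
regions with many narrow columns do not generate excess false peaks);
the fitted peak is bounded within ±60 nm of that init. Fits are flagged
non-converged when the width pins at its bounds, the amplitude
vanishes, or the peak lands on the window edge; flagged repeats are
excluded from precision and counted. In DWP mode, localizations farther
than roi/8 pixels from the known emitter are likewise rejected —
without these standard quality gates, sub-percent populations of
catastrophic fits at photon-starved conditions dominate the standard
deviation (e.g. 200+ nm errors against a ~30 nm core).

## Theory calculators

The localization bound is the Cramér–Rao-style expression for MLE
fitting of a pixelated Gaussian spot with uniform background (see
README), multiplied by FEM in variance because the simulated frames
carry EM excess noise; the bare bound is available via
`apply_fem=False`. The centroid bound adds the background/readout
kernel 1024·(σλ/c)³·(σy/ay)³/(aλN²) — σy in pixels — and the aλ²/12
floor. The excess-noise factor multiplies each photon-derived variance
term once; readout terms carry no EM factor. At the defaults these
calculators reproduce the expected sweep endpoints (10.5/15.0 nm
localization; ~1.9 nm centroid at N = 5000) and the Monte Carlo tracks
them with mean absolute errors of ~0.3 nm (localization) and ~1.7 nm
(centroid) over a 320–5000 photon sweep.

## Study conditions and problem sizes

Sweeps default to N = 700, b_bg = 15, peak 680 nm, FWHM 41 nm.
Theory-validation sweeps route all photons into the analyzed channel
with the uniform 5 nm/px dispersion, matching the assumptions of the
closed-form bounds. DWP-mode sweeps split a shared emitted budget; the
quoted N is the spatial-channel count of the reference R50:T50
splitter, so the emitted count is N/0.5 for every splitter under test
(the same source viewed through different beamsplitters — this is the
only reading consistent with both splitters' absolute precision levels
at the stated conditions). The beamsplitter comparison runs four
matched sweeps (photons 320–5000, background 0–50, peak 500–750 nm,
FWHM 10–80 nm; six points each) with identical seeds and grids and
averages the per-point percentage change in precision.

Precision runs use 2000–5000 repeats per condition (acceptance: 5000
for theory-mode points, ~3000 per peak-sweep point, ~500 per
beamsplitter point); the sampling error of a standard-deviation
estimate at R repeats is ≈ precision/√(2R), i.e. ~1% at 5000 repeats —
far below the validation tolerances. Seeding is hierarchical
(SeedSequence spawn keys per condition and repeat), so results are
bit-reproducible for a given master seed and independent of repeat
order.

## Known limitations

- No photoswitching kinetics, bleaching, multi-frame traces, 3D PSFs,
  drift, or multi-emitter overlap: every event is a single isolated
  emitter, so passing tests say nothing about dense-field artifacts.
- Efficiency curves default to wavelength-independent nominal R:T with
  optional flat excess loss; measured beamsplitter/prism spectra can be
  supplied as CSV but are not bundled. Quantities that depend on the
  *shape* of the real efficiency spectra (e.g. the exact average
  beamsplitter trade-off percentages) shift by several points between
  nominal and measured curves: with nominal lossless 30:70 splitting
  the closed-form bound itself predicts ≈ +43% average localization
  worsening over these grids, while milder (~+35%) values require the
  real curves' effective reflectance.
- The spectral-centroid variance at high background depends strongly on
  unstated pipeline conventions (window extent, negative-weight
  handling, background estimation). With the defaults here the centroid
  background sweep runs ~25% below a naive keep-all-weights analysis;
  alternative conventions are exposed in `SimConfig` rather than tuned.
- Background subtraction uses the known mean b_bg (the Z′ definition);
  estimating the background from neighbouring windows, as experimental
  pipelines must, adds variance not modelled here.
- The Gamma EMCCD model omits clock-induced charge, sCMOS-style
  pixel-dependent noise, and dark current (subsumed into b_bg).
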