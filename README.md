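# dwpsim

Monte Carlo simulation of **dual-wedge-prism (DWP) spectroscopic
single-molecule localization microscopy (sSMLM)**.

In sSMLM a dispersive element splits the photons of each single-molecule
blinking event into an undispersed *zeroth-order* spatial image and a
spectrally dispersed *first-order* image on the same EMCCD, so every
localization also carries an emission spectrum. The DWP design adds two
complications worth simulating before building or tuning an instrument:
a strongly **nonlinear spectral dispersion** across the 450–800 nm band,
and an **adjustable beamsplitter ratio** that trades localization
precision against spectral precision out of a fixed photon budget.

`dwpsim` models the full chain for users designing or analyzing such
systems: photon emission (lognormal or fixed counts, Gaussian or
tabulated emission spectra, wavelength-dependent Gaussian PSF),
beamsplitting through an efficiency function ε(λ), the empirical
rational dispersion function and its closed-form inverse with an affine
pixel calibration, EMCCD detection (pixelation, Poisson background B,
Gamma-distributed electron-multiplying gain, Gaussian readout noise R,
`Z = Γ(S+B, A)/U + R`), and estimation: bivariate-Gaussian Poisson-MLE
localization, spectral centroid, and 1D/2D least-squares spectral
fitting with dispersion-nonuniformity correction.

Precision is quantified as the standard deviation of the estimates over
repeated independent events, and is validated against closed-form
benchmarks: the localization bound

Δx² = FEM · (σx² + ax²/12)/N · (1 + 4τ + √(2τ/(1+4τ))),
τ = 2π(b_bg + b_ro²)(σx² + ax²/12)/(N ax²),

and the spectral-centroid bound

Δμλ² = FEM·(σλ²/(c²N) + 1024 b_bg (σλ/c)³(σy/ay)³/(aλN²))
     + 1024 b_ro² (σλ/c)³(σy/ay)³/(aλN²) + aλ²/12,

with FEM = 2 the EMCCD excess-noise variance factor and c = 2√(2 ln 2).

## Worked example

```python
import numpy as np
from dwpsim.experiments import (SimConfig, SweepSpec, run_sweep,
                                mc_theory_mae)

grid = [700, 1500, 5000]
sweep = run_sweep(SweepSpec(param="photons", grid=grid, mode="theory",
                            repeats=2000, seed=7,
                            estimators=("centroid",)))
print(sweep[["value", "loc_precision", "theory_loc",
             "centroid_precision"]].round(2).to_string(index=False))
print("MC-vs-theory localization MAE:",
      round(mc_theory_mae(sweep, "loc"), 2), "nm")
```

prints

```
 value  loc_precision  theory_loc  centroid_precision
 700.0          12.49       13.12                8.24
1500.0           7.83        7.90                4.98
5000.0           3.72        3.81                2.10
```

```
MC-vs-theory localization MAE: 0.26 nm
```

Each row is one simulated condition (default background 15 photons per
pixel, emission peak 680 nm, FWHM 41 nm, 160 nm pixels): at 1500
detected photons a single event localizes to ~7.8 nm; raising the
photon count to 5000 improves this to ~3.7 nm, and the spectral
centroid then pins the emission peak to ~2.1 nm — all tracking the
closed-form bounds.

There is also a thin CLI:

```bash
dwpsim sweep --param photons --grid 700,1500,5000 --repeats 1000 --seed 7 --out sweep.csv
dwpsim compare-bs --ratios 50:50,30:70 --repeats 300 --seed 7 --out bs.csv
dwpsim theory --sweep photons=320:5000:6 --json
dwpsim calibrate --centres 532,605,635,685,750
dwpsim fixture af647_like_spectrum --out-dir fixtures/
```

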