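# dynfc

Tools for asking how closely slow hemodynamic (BOLD-like) measures of
functional connectivity track the underlying electrophysiology — both in
space (how far coherent activity spreads across a cortical patch) and in
time (how connectivity between two regions fluctuates) — and for answering
that question separately for each local-field-potential (LFP) frequency band.

The package is aimed at systems/cognitive neuroscientists who work with
paired fMRI + microelectrode-array data (e.g. somatosensory cortex areas 3b
and 1 sampled with 7×7 Utah arrays at 400 µm pitch and sub-millimetre fMRI),
and at methodologists who want a fully synthetic, ground-truth-controlled
testbed for dynamic-functional-connectivity pipelines.

## What it computes

**Band decomposition.** Raw LFP-like signals (500 Hz) are band-passed with a
second-order zero-phase Chebyshev type-1 filter into delta (1–4 Hz), theta
(5–8), alpha (9–14), beta (15–30), gamma low (30–50), gamma high (50–100),
gamma very high (100–150) and broad band (1–150); band-limited power (BLP)
envelopes come from the analytic-signal magnitude.

**Spatial extent.** Magnitude-squared coherence
`MSC(f) = |Sxy(f)|² / (Sxx(f) Syy(f))` between a seed electrode and every
other electrode gives a per-band connectivity map; stimulus runs give
percent-power-change maps. Each map is normalized, its supra-0.7 centre of
mass located, profiles above 0.2 extracted along the major/minor axes, and
each profile fitted with a Gaussian `a·exp(−(x−µ)²/2σ²)`; the point-spread
function is summarized by `FWHM = 2√(2 ln 2)·σ` and the half-maximum ellipse
area `π·(FWHM_maj/2)·(FWHM_min/2)`.

**Temporal dynamics.** Sliding-window connectivity (60 s window, 3 s step —
one step per imaging volume) produces, per window, Pearson r for the slow
signals and band-averaged MSC (or BLP correlation) for the fast signals.
Each series is discretized into 50 equal connectivity states; the empirical
CDF of signed single-step state jumps summarizes the transition dynamics
(a first-order Markov view), and the two-sample Kolmogorov–Smirnov statistic
`D = sup|F_a − F_b|` measures how differently two modalities move between
states — lower D, more similar dynamics. The Fourier decomposition of the
windowed series attributes connectivity variation to fluctuation-frequency
bands (<0.0025, 0.0025–0.005, 0.005–0.01, 0.01–0.02, >0.02 Hz).

**Synthetic data.** Because the original recordings are not publicly
deposited, a first-class generator supplies every input: electrode grids
whose per-band coherence decays as a Gaussian of distance with a configurable
FWHM, elliptical activation blobs, 30 s on/off block-design runs, and a
coupled region pair whose coupling follows a hidden Markov chain expressed
with configurable fidelity in the slow signals and in each LFP band. Group
inference uses paired Wilcoxon signed-rank tests over 9 synthetic runs.

## Worked example

```python
import numpy as np
from dynfc import (GridGeometry, band_by_name, msc, band_average_msc,
                   fit_elliptical_psf, seed_coherence_map)
from dynfc.synth import generate_lfp_grid

# 7x7 grid, 400 um pitch, alpha-band coherence decaying with FWHM 1.2 mm
geom = GridGeometry(7, 7, 0.4)
alpha = band_by_name("alpha")
rec = generate_lfp_grid(geom, duration_s=120.0, fs=500.0,
                        band_powers={"alpha": 1.0},
                        coherence_fwhm_mm=1.2, seed=2, bands=(alpha,))

# neighbouring electrodes are 0.4 mm apart: the kernel predicts
# exp(-4 ln2 (0.4/1.2)^2) = 0.735
spec = msc(rec.data[24], rec.data[25], rec.fs)
print(f"MSC at 0.4 mm: {band_average_msc(spec, alpha):.3f}")

# seed-to-all map and its fitted point-spread function
smap = seed_coherence_map(rec, seed=24, band=alpha)
fit = fit_elliptical_psf(smap.values, major_axis_direction_rad=0.0)
print(f"fitted FWHM: {fit.fwhm_major_mm:.2f} mm, area: {fit.area_mm2:.2f} mm^2")
```

Output:

```
MSC at 0.4 mm: 0.702
fitted FWHM: 1.25 mm, area: 1.21 mm^2
```

The measured coherence sits at the analytic kernel value (0.735) up to Welch
estimator noise, and the fitted spatial profile recovers the configured
1.2 mm kernel width up to coarse-grid interpolation bias.

The full study pipeline runs from the command line:

```bash
dynfc all --seed 7 --out results_group/
```

which writes per-run windowed-connectivity tables, PSF fits, K-S profiles,
fluctuation-band fractions, and group Wilcoxon comparisons (plus a manifest
and the fully resolved configuration). Rerunning with the same seed
reproduces every table byte for byte.

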