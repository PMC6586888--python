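# Methods

This note documents the models and numerical procedures implemented in
`dynfc`, the choices made where the design was genuinely open, and what the
synthetic testbed does and does not establish about real data.

## Signals and estimators

### Band filtering

Fast signals are decomposed with a second-order Chebyshev type-1 band-pass
(0.5 dB passband ripple, configurable) applied forward and backward
(`sosfiltfilt`), giving zero phase at the cost of squaring the magnitude
response — in-band amplitudes can be attenuated up to twice the ripple, and
the effective stopband attenuation is doubled. Inputs are reflect-padded by
three periods of the band's lower edge; the padded spans are recorded in the
output metadata (`edge_span_s`) so downstream analyses can discount them.
The band table (delta 1–4 Hz through gamma-very-high 100–150 Hz, plus broad
band 1–150 Hz) is configurable via YAML; defaults are the conventional
macaque/squirrel-monkey LFP bands.

Band-limited power (BLP) is the magnitude of the analytic signal of the
band-passed trace, optionally smoothed with a moving average (default 0.5 s
in the pipeline — long enough to suppress carrier ripple, short relative to
the 3 s resampling used for envelope correlations). Full-wave rectification
is available as a cross-check variant.

### Coherence

Magnitude-squared coherence is Welch-estimated with 2 s Hann segments at 50%
overlap by default (the choice is exposed; all calibration tolerances in the
tests are quoted at these defaults). The per-band scalar used everywhere
downstream is the unweighted mean of the MSC over in-band frequency bins.
Two consequences of that reduction are worth knowing:

* the estimator bias for independent signals is ≈ 1/M for M averaged
  segments, so short windows have a visible coherence floor;
* the broad band (1–150 Hz) average is dominated *by bin count* by the
  50–150 Hz range, so broadband summaries track the high-frequency bands
  even when total signal power is concentrated at low frequencies. This is
  why the synthetic broadband results group with the gamma bands spatially
  even though the generator gives low frequencies most of the power.

Zero-variance channels make coherence undefined; they are flagged as missing
(NaN), never silently set to 0. `msc(x, x)` is exactly 1 bin-by-bin (the
implementation forms `|Sxy|²` without an `abs()` round-trip and canonicalizes
operand order, which also makes `msc(x, y) == msc(y, x)` bit-exact).

### Spatial point-spread functions

Activation and connectivity maps are normalized to unit maximum; the centre
of mass is the intensity-weighted centroid of the supra-0.7 region; profiles
along a caller-supplied major axis (and its perpendicular) keep the
contiguous stretch above 0.2 and are resampled at 0.10 mm by bilinear
interpolation (0.068 mm is appropriate for imaging-resolution maps). Each
profile is fitted with `a·exp(−(x−µ)²/2σ²)` (no baseline term by default; a
flag adds one) and summarized by FWHM = 2√(2 ln 2)·σ.

"Area" is operationalized as the half-maximum ellipse,
`π·(FWHM_maj/2)·(FWHM_min/2)`. This is a deliberate, prominent choice: other
contours would scale all areas by a constant and leave every within-package
comparison unchanged.

The two-profile sequential fit mirrors the classic activation-focus
procedure; a full 2-D elliptical Gaussian fit is provided as a cross-check
and agrees with the sequential fit to ~1% on noiseless blobs. On coarse maps
(7×7 electrodes at 0.4 mm) bilinear interpolation biases fitted widths by a
few percent; the bias is common to all conditions, so rest-vs-stimulation
*comparisons* are unaffected even where absolute widths are slightly off.

### Sliding-window dynamics and states

Window k covers `[k·step, k·step + W)`; the series length is
`floor((T − W)/step) + 1` (300 volumes at 3 s with a 60 s window and 3 s
step → 281 windows). Slow-signal connectivity is windowed Pearson r;
fast-signal connectivity is windowed band-averaged MSC, computed at the same
3 s step so the two modalities have matched sampling. Fisher z = arctanh(r)
is computed (|r| = 1 clipped to 1 − 1e-7) and recorded.

Discretization into 50 states uses equal half-open bins (last bin closed) on
[−1, 1] for correlation-based measures and [0, 1] for coherence-based ones,
so domain endpoints map to states 1 and 50 and jumps are in comparable state
units. Binning is applied to the bounded correlation scale rather than to
the unbounded z scale (arctanh has no finite [−1, 1] range; a flag,
`bin_on_z`, bins clipped z instead for sensitivity analysis). Missing
windows become missing states; no jump is counted across a gap, and the
dropped-transition count is recorded.

### Jump ECDFs and the K-S distance

The empirical CDF of *signed* single-step state jumps represents the
single-step transition law (the first-order Markov view: the next state
depends only on the present one). Two modalities are compared with the
two-sample Kolmogorov–Smirnov statistic, the supremum of the ECDF difference
over the union of observed jump values — computed exactly on that finite
grid, verified in the tests against both a brute-force enumeration and an
independent library implementation. The statistic is used as a distance
(lower = more similar dynamics); no p-value is attached to it. Group
inference is per-run K-S followed by paired Wilcoxon signed-rank across
runs. An |jump| variant and a Frobenius distance between empirical 50×50
transition matrices are available as diagnostics.

### Fluctuation spectra

The mean-removed windowed-connectivity series is decomposed with a raw
(untapered) periodogram — at ~281 points tapering costs resolution and the
five-band summary is insensitive to leakage at this scale (a taper flag
exists). The one-sided power normalization satisfies Parseval exactly
(non-DC bins sum to the series variance). The DC bin is excluded — the
analysis concerns variation, not mean level — and percentages are
accumulated in five bands (<0.0025, 0.0025–0.005, 0.005–0.01, 0.01–0.02,
>0.02 Hz; left-closed, right-open; the top band runs to the windowed-series
Nyquist 1/(2·step)). Normalization is per run, then averaged across runs.

## The synthetic testbed

### Spatially coherent grids

Each narrow band is an independent stationary Gaussian process per channel,
mixed through the Cholesky factor of the correlation matrix
`R_ij = exp(−2 ln 2 (d_ij/FWHM)²)` (a Gaussian RBF kernel, hence positive
definite). Since mixing is frequency-flat within the band, the band
coherence is `R_ij²`, i.e. the target MSC kernel
`exp(−4 ln 2 (d_ij/FWHM)²)` with the configured FWHM. Latent-source mixing
was chosen over explicit cross-spectral factorization for simplicity; the
calibration is empirical (tests verify the 0.5-coherence point of a 1.2 mm
kernel at 0.6 mm to ±0.1 with ≥60 Welch averages). The broad band is not
synthesized: it emerges in analysis as the mixture of the seven narrow-band
processes. Default band powers fall off 1/f-fashion (delta 1.0 down to
gamma-very-high 0.03); resting coherence levels have no published ground
truth, so kernel widths and powers are free parameters surfaced in the
configuration, not hard-coded.

### The coupled pair and fidelity

Inter-regional coupling follows a discrete-time Markov chain over coupling
strengths in [−1, 1] (default: five states 0.1–0.9, nearest-neighbour
switching with stay-probability 0.4, one step per 15 s; started from the
stationary distribution). The slow signals are 0.01–0.1 Hz band-limited
Gaussian noise generated directly — no hemodynamic-response convolution is
modelled — mixed so their instantaneous correlation equals the coupling
c(t). Each fast band carries the path with fidelity f through a target MSC
of `|f·c(t) + (1−f)·c̄|`, c̄ the stationary mean: fidelity 1 expresses the
full dynamics, fidelity 0 a *static* coupling at the same mean level.
Blending toward the static mean, rather than toward an independent
realization of the same chain, is deliberate: two independent realizations
of one chain share the same jump distribution in expectation, so a
jump-ECDF comparison could not tell fidelity 1 from fidelity 0. With the
static blend the low/high-fidelity contrast is identifiable, and the
measured K-S against the slow modality rises monotonically as fidelity
falls (tested over the sweep 1 → 0.5 → 0). Delta, theta and alpha
(≤15 Hz) take the low-band fidelity; beta and the gamma bands take the
high-band fidelity.

### Block designs and activation maps

Runs are off-then-on blocks (default 30 s/30 s × 7). Slow block-design
series add `amplitude × map` to the baseline during on-blocks (noiseless
percent change is exact by construction); fast series multiply each band's
carrier variance by `1 + amplitude × map_b(x)`, so per-band percent-power-
change maps are measurable from a single summed recording. Stimulus power
uses seconds 10–30 of each on-block (the onset transient is excluded);
baseline power uses the final 20 s of the preceding off period — anchoring
the pre-stimulus window to the end of the off block is the documented
convention here, as is using the *last* 7 of the 10 pre-onset volumes in the
volume-based variant.

### Study conditions and problem sizes

The default group is 9 runs (three synthetic "animals" × three runs):
dynamics runs of 900 s (300 volumes at 3 s; 500 Hz fast signals), spatial
runs with 120 s resting grids and 7-block stimulation runs on the 7×7,
0.4 mm grid. Default spatial kernels make resting coherence wider than the
stimulus response for the 5–30 Hz bands (e.g. theta 1.45 vs 1.00 mm FWHM)
and narrower for 50–150 Hz (e.g. gamma-high 0.75 vs 1.05 mm), with delta and
gamma-low near parity — the band-resolved contrast the spatial experiment is
designed to recover. These sizes keep a full group run at a few minutes on
one CPU while leaving the group Wilcoxon tests well away from their
detection threshold.

## What the synthetic results do and do not show

Passing tests establish that the estimators are calibrated (coherence
levels, Gaussian widths, window bookkeeping, spectral partition are
recovered at known tolerances) and that the *pipeline* recovers directions
that are true in the generator: when low-frequency bands carry the shared
coupling dynamics and high bands do not, the K-S profile says so in ≥8/9
runs; when spatial kernels are band-ordered, the fitted area tables are too.
They do not show that real cortex has these properties: the generator has no
hemodynamic response function, no scanner or physiological noise, no
nonstationarity beyond the Markov switching, stationary Gaussian marginals,
and frequency-flat within-band coupling. Two further internal caveats:
broadband summaries inherit the equal-bin-weight behaviour described above,
and the BLP-correlation route discriminates fidelity only weakly at these
window settings (its windowed series has nearly the same sampling structure
as the slow-signal series, so its jump ECDFs stay close to the slow
modality's regardless of band) — the coherence route is the sensitive one
in this testbed.

## Numerical details worth knowing

* Determinism: every generator takes a mandatory seed; a group run derives
  per-run sub-seeds from the master seed, and rerunning a configuration
  reproduces all output tables byte for byte.
* `fisher_z(±1)` is finite via the 1e-7 clip; the inverse is `tanh`.
* Welch estimation needs ≥2 segments; windows too short for that are
  rejected rather than silently degraded.
* Degenerate inputs: constant series → missing coherence/correlation;
  all-zero paired differences → Wilcoxon p = 1 with a degeneracy flag;
  <5 pairs → no p-value, flagged `insufficient_n`; empty supra-threshold
  sets and sub-floor profile centres raise with a message naming the check.
* Gaussian fits start from moment-based initial values; non-convergence
  raises with residual diagnostics attached rather than returning garbage.
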