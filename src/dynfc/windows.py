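"""Sliding-window connectivity and discretization into putative brain states.

A window of length W seconds is stepped in increments of `step` seconds (3 s by
default, the volume interval of the slow modality); window k covers
``[k*step, k*step + W)`` and the series has ``floor((T - W)/step) + 1`` entries.
Correlation-based series live on [-1, 1], coherence-based series on [0, 1];
both are discretized into 50 equal bins ("states") on their domain, so that
single-step jumps are expressed in comparable state units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import FrequencyBand
from .coherence import DEFAULT_OVERLAP, DEFAULT_SEGMENT_S, band_average_msc, msc

__all__ = [
    "WindowedConnectivity",
    "StateSequence",
    "window_count",
    "sliding_correlation",
    "sliding_band_coherence",
    "sliding_coherence_profiles",
    "fisher_z",
    "inverse_fisher_z",
    "bin_states",
    "R_CLIP",
]

#: |r| = 1 is clipped to 1 - R_CLIP before the Fisher transform.
R_CLIP = 1e-7

DEFAULT_N_STATES = 50
R_DOMAIN = (-1.0, 1.0)
MSC_DOMAIN = (0.0, 1.0)


@dataclass
class WindowedConnectivity:
    values: np.ndarray
    window_length_s: float
    step_s: float
    measure: str  # pearson_r | band_msc | blp_r
    band: FrequencyBand | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_windows(self) -> int:
        return self.values.size

    def window_starts_s(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step_s

    def domain(self) -> tuple[float, float]:
        return MSC_DOMAIN if self.measure == "band_msc" else R_DOMAIN


@dataclass
class StateSequence:
    """Integer states 1..n_states with an explicit missing mask."""

    states: np.ndarray
    n_states: int
    domain: tuple[float, float]
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int).ravel()
        if self.missing is None:
            self.missing = np.zeros(self.states.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool).ravel()
        if self.missing.shape != self.states.shape:
            raise ValueError("missing mask must match the state sequence length")
        ok = self.states[~self.missing]
        if ok.size and (ok.min() < 1 or ok.max() > self.n_states):
            raise ValueError("states must lie in 1..n_states")

    def __len__(self) -> int:
        return self.states.size


def window_count(n_samples: int, window_samples: int, step_samples: int) -> int:
    if window_samples > n_samples:
        raise ValueError(f"window ({window_samples}) longer than series ({n_samples})")
    return (n_samples - window_samples) // step_samples + 1


def _window_samples(window_length_s: float, step_s: float, dt: float) -> tuple[int, int]:
    w = int(round(window_length_s / dt))
    s = int(round(step_s / dt))
    if s < 1:
        raise ValueError(f"step {step_s}s is below one sample interval ({dt}s)")
    return w, s


def sliding_correlation(
    a: np.ndarray,
    b: np.ndarray,
    window_length_s: float,
    step_s: float,
    sample_interval_s: float,
    *,
    measure: str = "pearson_r",
) -> WindowedConnectivity:
    """Pearson r in each sliding window; zero-variance windows give NaN."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.size} vs {b.size}")
    w, s = _window_samples(window_length_s, step_s, sample_interval_s)
    if w < 3:
        raise ValueError("window must span at least 3 samples")
    n_win = window_count(a.size, w, s)
    values = np.full(n_win, np.nan)
    for k in range(n_win):
        xa = a[k * s : k * s + w]
        xb = b[k * s : k * s + w]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue  # missing value, kept as NaN
        values[k] = np.corrcoef(xa, xb)[0, 1]
    return WindowedConnectivity(values, window_length_s, step_s, measure)


def sliding_coherence_profiles(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    bands: tuple[FrequencyBand, ...],
    window_length_s: float,
    step_s: float,
    *,
    segment_length_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> dict[str, WindowedConnectivity]:
    """Band-averaged MSC per sliding window for several bands at once.

    The coherence spectrum is estimated once per window and then reduced per
    band, which keeps multi-band sweeps at the cost of a single-band one.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    dt = 1.0 / fs
    w, s = _window_samples(window_length_s, step_s, dt)
    nperseg = int(round(segment_length_s * fs))
    hop = nperseg - int(nperseg * overlap)
    if w < nperseg + hop:  # guarantee at least two Welch segments per window
        raise ValueError("window too short for two Welch segments at these settings")
    n_win = window_count(x.size, w, s)
    out = {band.name: np.full(n_win, np.nan) for band in bands}
    for k in range(n_win):
        xs = x[k * s : k * s + w]
        ys = y[k * s : k * s + w]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        spec = msc(xs, ys, fs, segment_length_s, overlap)
        for band in bands:
            out[band.name][k] = band_average_msc(spec, band)
    return {
        band.name: WindowedConnectivity(
            out[band.name], window_length_s, step_s, "band_msc", band
        )
        for band in bands
    }


def sliding_band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: FrequencyBand,
    window_length_s: float,
    step_s: float,
    *,
    segment_length_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> WindowedConnectivity:
    """Band-averaged MSC in each sliding window (single-band convenience)."""
    return sliding_coherence_profiles(
        x, y, fs, (band,), window_length_s, step_s,
        segment_length_s=segment_length_s, overlap=overlap,
    )[band.name]


def fisher_z(r):
    """arctanh with |r| = 1 clipped to 1 - 1e-7."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + R_CLIP, 1.0 - R_CLIP)
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(np.asarray(z, dtype=float))


def bin_states(
    values: np.ndarray | WindowedConnectivity,
    n_states: int = DEFAULT_N_STATES,
    domain: tuple[float, float] | None = None,
) -> StateSequence:
    """Discretize a connectivity series into equal-width states 1..n_states.

    Values are clamped to the domain, then assigned to half-open bins
    ``[edge_k, edge_{k+1})`` with the last bin closed, so the domain endpoints
    map to states 1 and n_states.  NaNs become missing states (excluded from
    jump counting downstream, with the count recorded).
    """
    if isinstance(values, WindowedConnectivity):
        if domain is None:
            domain = values.domain()
        values = values.values
    if domain is None:
        raise ValueError("domain required when binning a bare array")
    lo, hi = domain
    if not lo < hi:
        raise ValueError(f"domain must satisfy lo < hi, got {domain}")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    v = np.asarray(values, dtype=float).ravel()
    missing = ~np.isfinite(v)
    clamped = np.clip(v, lo, hi)
    clamped[missing] = lo  # placeholder under the mask
    width = (hi - lo) / n_states
    states = np.floor((clamped - lo) / width).astype(int) + 1
    states = np.minimum(states, n_states)
    return StateSequence(states, n_states, (lo, hi), missing)
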