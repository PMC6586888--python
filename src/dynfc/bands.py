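"""Frequency-band decomposition of raw fast (LFP-like) signals.

The canonical band table splits 1-150 Hz into seven disjoint ranges plus a
broad band covering the whole range.  Band-pass filtering uses a second-order
Chebyshev type-1 filter applied forward and backward (zero phase); the
effective magnitude response is therefore the squared single-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import fft, signal
from scipy.ndimage import uniform_filter1d

from .containers import MultiChannelRecording

__all__ = [
    "FrequencyBand",
    "DEFAULT_BANDS",
    "NARROW_BANDS",
    "BROADBAND",
    "band_by_name",
    "load_band_table",
    "bandpass",
    "Spectrogram",
    "spectrogram_db",
    "band_limited_power",
]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r} requires 0 < f_low < f_high, got "
                f"({self.f_low}, {self.f_high})"
            )

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        return (freqs >= self.f_low) & (freqs <= self.f_high)


#: The seven disjoint narrow bands.
NARROW_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 1.0, 4.0),
    FrequencyBand("theta", 5.0, 8.0),
    FrequencyBand("alpha", 9.0, 14.0),
    FrequencyBand("beta", 15.0, 30.0),
    FrequencyBand("gamma_low", 30.0, 50.0),
    FrequencyBand("gamma_high", 50.0, 100.0),
    FrequencyBand("gamma_very_high", 100.0, 150.0),
)

BROADBAND = FrequencyBand("broadband", 1.0, 150.0)

#: The eight analysis bands (seven narrow + broad band).
DEFAULT_BANDS: tuple[FrequencyBand, ...] = NARROW_BANDS + (BROADBAND,)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> FrequencyBand:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


def load_band_table(path) -> tuple[FrequencyBand, ...]:
    """Read a YAML/JSON list of ``{name, f_low, f_high}`` entries."""
    with open(path) as f:
        entries = yaml.safe_load(f)
    return tuple(FrequencyBand(e["name"], float(e["f_low"]), float(e["f_high"])) for e in entries)


def _cheby1_sos(band: FrequencyBand, fs: float, order: int, ripple_db: float) -> np.ndarray:
    nyq = fs / 2.0
    if band.f_high >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_high} Hz is at or above the "
            f"Nyquist frequency {nyq} Hz"
        )
    return signal.cheby1(
        order, ripple_db, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos"
    )


def _zero_phase_padlen(band: FrequencyBand, fs: float, n_samples: int) -> int:
    # reflect-pad by three times the slowest in-band period; capped by signal length
    settle = int(np.ceil(3.0 * fs / band.f_low))
    return int(min(n_samples - 1, settle))


def bandpass(
    recording: MultiChannelRecording,
    band: FrequencyBand,
    *,
    order: int = 2,
    ripple_db: float = 0.5,
) -> MultiChannelRecording:
    """Zero-phase Chebyshev type-1 band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the output
    has no group delay and the effective attenuation is squared.  The input is
    reflect-padded by three slowest-period lengths; the first/last padded spans
    are flagged in the output metadata.
    """
    sos = _cheby1_sos(band, recording.fs, order, ripple_db)
    padlen = _zero_phase_padlen(band, recording.fs, recording.n_samples)
    if recording.n_samples <= 3 * (2 * order + 1):
        raise ValueError("signal too short for zero-phase filtering")
    out = signal.sosfiltfilt(sos, recording.data, axis=1, padtype="even", padlen=padlen)
    meta = dict(recording.meta)
    meta.update(
        band=band.name,
        band_edges_hz=[band.f_low, band.f_high],
        filter="cheby1",
        filter_order=order,
        ripple_db=ripple_db,
        zero_phase=True,
        edge_span_s=padlen / recording.fs,
    )
    return MultiChannelRecording(out, recording.fs, recording.geometry, meta)


@dataclass
class Spectrogram:
    """Trial-averaged power in dB: ``power_db[freq, time]``."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power_db: np.ndarray
    meta: dict = field(default_factory=dict)


def spectrogram_db(
    recording: MultiChannelRecording,
    window_length_s: float = 1.0,
    overlap: float = 0.5,
    *,
    trial_length_s: float | None = None,
    db_floor: float = -120.0,
) -> Spectrogram:
    """Channel- and trial-averaged spectrogram on a dB (10*log10) scale.

    If ``trial_length_s`` is given, each channel is cut into consecutive trials
    of that length and the per-trial power spectrograms are averaged before the
    dB conversion.  Zero-power cells are clamped to ``db_floor`` instead of -inf.
    """
    fs = recording.fs
    nperseg = int(round(window_length_s * fs))
    if nperseg < 8:
        raise ValueError("window_length_s too short: need at least 8 samples per window")
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    noverlap = int(nperseg * overlap)

    if trial_length_s is None:
        segments = recording.data
    else:
        per_trial = int(round(trial_length_s * fs))
        n_trials = recording.n_samples // per_trial
        if n_trials < 1:
            raise ValueError("trial_length_s longer than the recording")
        segments = recording.data[:, : n_trials * per_trial].reshape(-1, per_trial)

    freqs, times, sxx = signal.spectrogram(
        segments, fs=fs, nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    mean_power = sxx.mean(axis=0)  # average trials x channels
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(mean_power)
    power_db = np.maximum(power_db, db_floor)
    return Spectrogram(
        times, freqs, power_db, {"window_length_s": window_length_s, "overlap": overlap}
    )


def band_limited_power(
    recording: MultiChannelRecording,
    band: FrequencyBand,
    smoothing_s: float = 0.0,
    *,
    method: str = "hilbert",
    order: int = 2,
    ripple_db: float = 0.5,
) -> MultiChannelRecording:
    """Band-limited power envelope: analytic-signal magnitude of the band-passed
    signal, optionally smoothed with a moving average of ``smoothing_s`` seconds.

    ``method='rectify'`` replaces the analytic-signal magnitude by full-wave
    rectification (then the same smoothing), offered as a cross-check variant.
    """
    bp = bandpass(recording, band, order=order, ripple_db=ripple_db)
    if method == "hilbert":
        n_fft = int(fft.next_fast_len(bp.n_samples))
        analytic = signal.hilbert(bp.data, N=n_fft, axis=1)[:, : bp.n_samples]
        env = np.abs(analytic)
    elif method == "rectify":
        env = np.abs(bp.data)
    else:
        raise ValueError(f"unknown BLP method {method!r}")

    n_smooth = int(round(smoothing_s * recording.fs))
    if n_smooth > 1:  # shorter than one sample means no smoothing
        env = uniform_filter1d(env, size=n_smooth, axis=1, mode="nearest")
    meta = dict(bp.meta)
    meta.update(measure="blp", smoothing_s=smoothing_s, blp_method=method)
    return MultiChannelRecording(env, recording.fs, recording.geometry, meta)
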