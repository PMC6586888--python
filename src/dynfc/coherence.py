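"""Magnitude-squared coherence (MSC) and stimulus-evoked power-change maps.

MSC is the Welch-averaged ``|Sxy|^2 / (Sxx * Syy)`` on [0, 1].  The per-band
scalar used throughout the package is the arithmetic mean of the MSC over the
frequency bins falling inside the band.  Default Welch settings are 2 s Hann
segments with 50% overlap; all calibration tolerances elsewhere are quoted at
these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import FrequencyBand, bandpass
from .containers import MultiChannelRecording, SpatialMap, StimulusParadigm

__all__ = [
    "CoherenceSpectrum",
    "SeedMap",
    "msc",
    "band_average_msc",
    "seed_coherence_map",
    "stimulus_power_change_map",
]

DEFAULT_SEGMENT_S = 2.0
DEFAULT_OVERLAP = 0.5
_CLIP_TOL = 1e-12


@dataclass
class CoherenceSpectrum:
    freqs_hz: np.ndarray
    msc: np.ndarray
    n_averages: int
    meta: dict = field(default_factory=dict)


@dataclass
class SeedMap:
    """Per-channel connectivity with one seed; ``values.values[seed] == 1``."""

    seed_index: int
    values: SpatialMap
    meta: dict = field(default_factory=dict)


def _n_welch_segments(n_samples: int, nperseg: int, noverlap: int) -> int:
    if n_samples < nperseg:
        return 0
    return 1 + (n_samples - nperseg) // (nperseg - noverlap)


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    segment_length_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
    *,
    window: str = "hann",
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence between two equal-length series.

    A constant (zero-variance) input makes coherence undefined; the spectrum is
    then returned as all-NaN and flagged in ``meta['undefined']`` rather than 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    nperseg = int(round(segment_length_s * fs))
    if nperseg < 2:
        raise ValueError("segment_length_s too short for the sampling rate")
    noverlap = int(nperseg * overlap)
    n_avg = _n_welch_segments(x.size, nperseg, noverlap)
    if n_avg < 2:
        raise ValueError(
            f"need at least 2 Welch segments, got {n_avg} "
            f"(n={x.size}, nperseg={nperseg}, noverlap={noverlap})"
        )
    meta = {"segment_length_s": segment_length_s, "overlap": overlap, "window": window}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
        meta["undefined"] = True
        return CoherenceSpectrum(freqs, np.full(freqs.shape, np.nan), n_avg, meta)

    if y is not x and np.array_equal(x, y):
        y = x  # same-data fast path keeps the cross-spectrum exactly real
    elif y is not x and x.tobytes() > y.tobytes():
        x, y = y, x  # canonical operand order: msc(x, y) == msc(y, x) bit-exactly
    welch_kw = dict(fs=fs, window=window, nperseg=nperseg, noverlap=noverlap, detrend="constant")
    freqs, pxy = signal.csd(x, y, **welch_kw)
    _, pxx = signal.welch(x, **welch_kw)
    _, pyy = signal.welch(y, **welch_kw)
    # |Pxy|^2 without the sqrt/square round-trip of abs(), so msc(x, x) is
    # exactly 1 bin by bin
    cxy = (pxy.real**2 + pxy.imag**2) / (pxx * pyy)
    # clip only floating-point excursions
    cxy = np.where((cxy < 0) & (cxy > -_CLIP_TOL), 0.0, cxy)
    cxy = np.where((cxy > 1) & (cxy < 1 + _CLIP_TOL), 1.0, cxy)
    return CoherenceSpectrum(freqs, cxy, n_avg, meta)


def band_average_msc(spec: CoherenceSpectrum, band: FrequencyBand) -> float:
    """Mean MSC over the frequency bins with ``f_low <= f <= f_high``."""
    mask = band.contains(spec.freqs_hz)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} ({band.f_low}-{band.f_high} Hz) overlaps no frequency bin"
        )
    return float(np.mean(spec.msc[mask]))


def seed_coherence_map(
    recording: MultiChannelRecording,
    seed: int,
    band: FrequencyBand,
    *,
    segment_length_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> SeedMap:
    """Band-averaged MSC between one seed electrode and every electrode,
    arranged on the grid.  Dead (zero-variance) channels are NaN."""
    if recording.geometry is None:
        raise ValueError("seed_coherence_map requires a recording with grid geometry")
    n_ch = recording.n_channels
    if not 0 <= seed < n_ch:
        raise ValueError(f"seed {seed} outside 0..{n_ch - 1}")
    values = np.full(n_ch, np.nan)
    xs = recording.data[seed]
    seed_dead = np.ptp(xs) == 0
    for ch in range(n_ch):
        if ch == seed:
            values[ch] = np.nan if seed_dead else 1.0
            continue
        if seed_dead or np.ptp(recording.data[ch]) == 0:
            continue
        spec = msc(xs, recording.data[ch], recording.fs, segment_length_s, overlap)
        values[ch] = band_average_msc(spec, band)
    grid = values.reshape(recording.geometry.shape)
    smap = SpatialMap(
        grid,
        recording.geometry.spacing_mm,
        {"band": band.name, "seed_index": seed, "measure": "band_msc"},
    )
    return SeedMap(seed, smap, {"band": band.name})


def stimulus_power_change_map(
    recording: MultiChannelRecording,
    paradigm: StimulusParadigm,
    band: FrequencyBand,
    *,
    discard_onset_s: float = 10.0,
    analysis_window_s: float = 20.0,
    normalize: bool = True,
) -> SpatialMap:
    """Per-channel percent change of band power between stimulation and
    pre-stimulus baseline, block-averaged.

    Stimulus power uses the window ``[onset + discard_onset_s, onset + discard_onset_s
    + analysis_window_s)`` of each on-block (the first seconds after onset are
    excluded so only the steady-state response is measured); baseline power uses
    the final ``analysis_window_s`` seconds of the preceding off period.  With
    ``normalize=True`` the map is scaled to its maximum value for the run.
    """
    if paradigm.block_on_s < discard_onset_s + analysis_window_s:
        raise ValueError(
            "on-blocks must cover the discarded onset plus the analysis window "
            f"({discard_onset_s}+{analysis_window_s}s, got {paradigm.block_on_s}s)"
        )
    if paradigm.block_off_s < analysis_window_s:
        raise ValueError("off-blocks shorter than the baseline analysis window")
    if recording.duration_s < paradigm.total_duration_s - 1.0 / recording.fs:
        raise ValueError("recording shorter than the stimulus paradigm")
    if recording.geometry is None:
        raise ValueError("stimulus_power_change_map requires grid geometry")

    bp = bandpass(recording, band)
    fs = recording.fs
    changes = np.zeros((paradigm.n_blocks, recording.n_channels))
    valid = np.ones(recording.n_channels, dtype=bool)
    for k, (on_start, _on_end) in enumerate(paradigm.on_intervals_s()):
        stim_i0 = int(round((on_start + discard_onset_s) * fs))
        stim_i1 = int(round((on_start + discard_onset_s + analysis_window_s) * fs))
        pre_i0 = int(round((on_start - analysis_window_s) * fs))
        pre_i1 = int(round(on_start * fs))
        p_stim = np.mean(bp.data[:, stim_i0:stim_i1] ** 2, axis=1)
        p_pre = np.mean(bp.data[:, pre_i0:pre_i1] ** 2, axis=1)
        ok = p_pre > 0
        valid &= ok
        with np.errstate(divide="ignore", invalid="ignore"):
            changes[k] = 100.0 * (p_stim - p_pre) / p_pre
    mean_change = changes.mean(axis=0)
    mean_change[~valid] = np.nan
    meta = {
        "band": band.name,
        "measure": "percent_power_change",
        "max_percent_change": float(np.nanmax(mean_change)),
        "discard_onset_s": discard_onset_s,
        "analysis_window_s": analysis_window_s,
        "normalized": normalize,
    }
    if normalize:
        vmax = np.nanmax(mean_change)
        if vmax > 0:
            mean_change = mean_change / vmax
    return SpatialMap(
        mean_change.reshape(recording.geometry.shape), recording.geometry.spacing_mm, meta
    )
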