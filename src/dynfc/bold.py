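"""Slow-signal (hemodynamic-like) preparation: temporal band filtering,
block-design percent-change activation maps, seed selection and seed-based
correlation maps.

Only the steps that apply to clean synthetic data are implemented; scanner-
specific corrections (motion, slice timing, drift, physiological noise) are
deliberately absent and recorded as skipped in the provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .coherence import SeedMap
from .containers import SpatialMap, StimulusParadigm, VolumeSeries

__all__ = [
    "ActivationResult",
    "bandpass_slow",
    "percent_change_map",
    "seed_correlation_map",
]

SKIPPED_PREPROCESSING = (
    "motion_correction",
    "slice_timing",
    "drift_correction",
    "physiological_noise_regression",
)


@dataclass
class ActivationResult:
    """Normalized percent-signal-change map plus the peak-response seeds."""

    map: SpatialMap
    seeds: dict[str, int]  # region label -> flat voxel index attaining the region max
    raw_percent: np.ndarray = None
    meta: dict = field(default_factory=dict)


def bandpass_slow(
    series: VolumeSeries,
    f_low_hz: float = 0.01,
    f_high_hz: float = 0.1,
    *,
    order: int = 2,
) -> VolumeSeries:
    """Zero-phase Butterworth band-pass between the stated corner frequencies.

    The corner pair (0.01-0.1 Hz) is the conventional slow-fluctuation range;
    DC and drifts below ``f_low_hz`` are removed.
    """
    if series.duration_s < 2.0 / f_low_hz:
        raise ValueError(
            f"series duration {series.duration_s:.0f}s is shorter than two cycles "
            f"of the low corner ({2.0 / f_low_hz:.0f}s)"
        )
    nyq = series.fs / 2.0
    if f_high_hz >= nyq:
        raise ValueError(f"f_high {f_high_hz} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(order, [f_low_hz, f_high_hz], btype="bandpass", fs=series.fs, output="sos")
    out = signal.sosfiltfilt(sos, series.data, axis=0)
    meta = dict(series.meta)
    meta.update(
        bandpass_hz=[f_low_hz, f_high_hz],
        filter="butter",
        zero_phase=True,
        skipped_preprocessing=list(SKIPPED_PREPROCESSING),
    )
    return VolumeSeries(out, series.volume_interval_s, list(series.labels), meta)


def percent_change_map(
    series: VolumeSeries,
    paradigm: StimulusParadigm,
    *,
    grid_shape: tuple[int, int] | None = None,
    resolution_mm: float = 1.0,
    regions: np.ndarray | None = None,
    n_on_volumes: int = 10,
    n_pre_volumes: int = 7,
    pre_window_volumes: int = 10,
) -> ActivationResult:
    """Block-averaged percent signal change per voxel, normalized per region.

    For each on-block, the stimulus mean uses the first ``n_on_volumes`` volumes
    from onset and the baseline mean uses ``n_pre_volumes`` of the
    ``pre_window_volumes`` volumes immediately before onset (the last ones, a
    documented choice).  Maps are normalized to each region's own maximum; the
    per-region argmax voxel is returned as the seed.
    """
    vi = series.volume_interval_s
    n_vox = series.data.shape[1]
    if regions is None:
        regions = np.zeros(n_vox, dtype=int)
    regions = np.asarray(regions).ravel()
    if regions.size != n_vox:
        raise ValueError("regions must label every voxel/series")

    onsets = [int(round(start / vi)) for start, _ in paradigm.on_intervals_s()]
    per_block = np.zeros((len(onsets), n_vox))
    valid = np.ones(n_vox, dtype=bool)
    for k, onset in enumerate(onsets):
        if onset + n_on_volumes > series.n_volumes or onset - n_pre_volumes < 0:
            raise ValueError("block timing extends outside the acquired series")
        stim = series.data[onset : onset + n_on_volumes].mean(axis=0)
        pre = series.data[onset - n_pre_volumes : onset].mean(axis=0)
        ok = pre != 0
        valid &= ok
        with np.errstate(divide="ignore", invalid="ignore"):
            per_block[k] = 100.0 * (stim - pre) / pre
    raw = per_block.mean(axis=0)
    raw[~valid] = np.nan

    normalized = np.full(n_vox, np.nan)
    seeds: dict[str, int] = {}
    for label in np.unique(regions):
        sel = regions == label
        region_vals = raw[sel]
        if np.all(np.isnan(region_vals)):
            continue
        vmax = np.nanmax(region_vals)
        idx_region = np.flatnonzero(sel)
        seeds[str(label)] = int(idx_region[np.nanargmax(region_vals)])
        normalized[sel] = region_vals / vmax if vmax > 0 else region_vals

    if grid_shape is None:
        grid_shape = (1, n_vox)
    smap = SpatialMap(
        normalized.reshape(grid_shape),
        resolution_mm,
        {
            "measure": "percent_bold_change_normalized",
            "n_on_volumes": n_on_volumes,
            "n_pre_volumes": n_pre_volumes,
            "skipped_preprocessing": list(SKIPPED_PREPROCESSING),
        },
    )
    return ActivationResult(smap, seeds, raw, {"n_blocks": len(onsets)})


def seed_correlation_map(
    series: VolumeSeries,
    seed: int,
    *,
    grid_shape: tuple[int, int] | None = None,
    resolution_mm: float = 1.0,
) -> SeedMap:
    """Pearson r of every voxel's series with the seed series; self = 1;
    zero-variance voxels are missing (NaN)."""
    n_vox = series.data.shape[1]
    if not 0 <= seed < n_vox:
        raise ValueError(f"seed {seed} outside 0..{n_vox - 1}")
    x = series.data[:, seed]
    if np.ptp(x) == 0:
        raise ValueError("seed series has zero variance")
    values = np.full(n_vox, np.nan)
    xc = x - x.mean()
    xn = np.sqrt(np.sum(xc**2))
    for v in range(n_vox):
        if v == seed:
            values[v] = 1.0
            continue
        y = series.data[:, v]
        if np.ptp(y) == 0:
            continue
        yc = y - y.mean()
        values[v] = float(np.dot(xc, yc) / (xn * np.sqrt(np.sum(yc**2))))
    if grid_shape is None:
        grid_shape = (1, n_vox)
    smap = SpatialMap(
        values.reshape(grid_shape), resolution_mm, {"measure": "pearson_r", "seed_index": seed}
    )
    return SeedMap(seed, smap)
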