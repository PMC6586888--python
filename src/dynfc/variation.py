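"""Fourier decomposition of windowed-connectivity fluctuations.

The mean-removed windowed series is decomposed with a raw (untapered)
periodogram; power is expressed as percentages of the total (the DC bin is
excluded: the analysis concerns variation, not mean level) and accumulated in
five fluctuation-frequency bands:

    < 0.0025 Hz | 0.0025-0.005 Hz | 0.005-0.01 Hz | 0.01-0.02 Hz | > 0.02 Hz

Band edges are closed on the left and open on the right; the top band extends
to the windowed-series Nyquist frequency 1/(2*step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowedConnectivity

__all__ = [
    "FLUCTUATION_BAND_EDGES",
    "FLUCTUATION_BAND_NAMES",
    "VariationSpectrum",
    "variation_spectrum",
    "compare_band_variation",
]

FLUCTUATION_BAND_EDGES = (0.0025, 0.005, 0.01, 0.02)
FLUCTUATION_BAND_NAMES = (
    "lt_0.0025Hz",
    "0.0025-0.005Hz",
    "0.005-0.01Hz",
    "0.01-0.02Hz",
    "gt_0.02Hz",
)


@dataclass
class VariationSpectrum:
    freqs_hz: np.ndarray
    percent: np.ndarray  # sums to 100 over the non-DC bins
    cumulative_bands: dict[str, float]  # the five named fractions, summing to 100
    total_power: float
    meta: dict = field(default_factory=dict)


def variation_spectrum(
    wc: WindowedConnectivity, *, taper: str | None = None, min_windows: int = 16
) -> VariationSpectrum:
    """Raw periodogram of a windowed-connectivity series as percentages.

    The power normalization satisfies Parseval: the non-DC periodogram bins sum
    to the variance of the mean-removed series.
    """
    v = np.asarray(wc.values, dtype=float)
    if v.size < min_windows:
        raise ValueError(f"need at least {min_windows} windows, got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError("windowed series contains missing values")
    if not wc.step_s > 0:
        raise ValueError("windowed series must have a positive uniform step")
    n = v.size
    x = v - v.mean()
    if taper is not None:
        from scipy.signal import get_window

        x = x * get_window(taper, n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=wc.step_s)
    # one-sided power with Parseval scaling: sum(power) == mean(x**2)
    power = np.abs(spec) ** 2 / n**2
    scale = np.full(power.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale

    freqs_nz = freqs[1:]
    power_nz = power[1:]
    total = float(power_nz.sum())
    if total == 0:
        raise ValueError("windowed series has zero variance; no variation to decompose")
    percent = 100.0 * power_nz / total

    edges = (0.0,) + FLUCTUATION_BAND_EDGES + (np.inf,)
    bands = {}
    for name, lo, hi in zip(FLUCTUATION_BAND_NAMES, edges[:-1], edges[1:]):
        mask = (freqs_nz >= lo) & (freqs_nz < hi)
        bands[name] = float(percent[mask].sum())
    return VariationSpectrum(
        freqs_nz,
        percent,
        bands,
        total,
        {
            "frequency_resolution_hz": 1.0 / (n * wc.step_s),
            "nyquist_hz": 1.0 / (2.0 * wc.step_s),
            "taper": taper,
            "measure": wc.measure,
        },
    )


def compare_band_variation(
    spectra_by_condition: dict[str, list[VariationSpectrum]],
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests per fluctuation band between every
    pair of conditions (runs are paired by position in each list)."""
    names = list(spectra_by_condition)
    if len(names) < 2:
        raise ValueError("need at least two conditions to compare")
    lengths = {name: len(spectra_by_condition[name]) for name in names}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"conditions have unpaired run counts: {lengths}")
    n_runs = next(iter(lengths.values()))
    if n_runs < 2:
        raise ValueError("insufficient n: need at least two paired runs")

    rows = []
    for i, cond_a in enumerate(names):
        for cond_b in names[i + 1 :]:
            for band in FLUCTUATION_BAND_NAMES:
                a = np.array([s.cumulative_bands[band] for s in spectra_by_condition[cond_a]])
                b = np.array([s.cumulative_bands[band] for s in spectra_by_condition[cond_b]])
                diffs = a - b
                if np.all(diffs == 0):
                    stat, p, degenerate = 0.0, 1.0, True
                else:
                    res = stats.wilcoxon(a, b)
                    stat, p, degenerate = float(res.statistic), float(res.pvalue), False
                rows.append(
                    {
                        "condition_a": cond_a,
                        "condition_b": cond_b,
                        "fluctuation_band": band,
                        "mean_a": float(a.mean()),
                        "mean_b": float(b.mean()),
                        "wilcoxon_statistic": stat,
                        "p_value": p,
                        "degenerate": degenerate,
                        "n_pairs": n_runs,
                    }
                )
    return pd.DataFrame(rows)
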