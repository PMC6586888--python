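"""Synthetic generators for every input the analyses consume.

The generators emulate the statistical structure the downstream stages assume:

* an electrode grid whose per-band pairwise coherence decays as a Gaussian of
  inter-electrode distance (latent band-limited sources mixed through the
  matrix square root of a Gaussian-kernel correlation matrix);
* a pair of regions whose inter-regional coupling follows a hidden Markov
  state path, expressed with configurable fidelity in the slow (hemodynamic-
  like, 0.01-0.1 Hz) signals and in each fast frequency band;
* elliptical-Gaussian activation blobs and 30 s on/off block-design runs.

Only the seven disjoint narrow bands are synthesized; the broad band (1-150 Hz)
emerges in analysis as their power-weighted mixture, which is why broadband
measurements behave like the (power-dominant) low-frequency bands.

Every generator takes a mandatory integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import NARROW_BANDS, FrequencyBand
from .containers import (
    GridGeometry,
    MultiChannelRecording,
    SpatialMap,
    StimulusParadigm,
    VolumeSeries,
)

__all__ = [
    "CouplingStateModel",
    "CoupledPair",
    "DEFAULT_BAND_POWERS",
    "DEFAULT_COUPLING_MODEL",
    "SLOW_BAND_HZ",
    "LOW_GROUP_MAX_HZ",
    "band_fidelity",
    "generate_lfp_grid",
    "generate_coupled_pair",
    "generate_activation_map",
    "generate_block_design_series",
    "generate_stim_lfp_grid",
]

#: Slow-signal passband (Hz): the conventional hemodynamic fluctuation range.
SLOW_BAND_HZ = (0.01, 0.1)

#: Bands whose upper edge is at or below this are the "low-frequency" group
#: (delta/theta/alpha, 1-15 Hz); the rest (15-150 Hz) form the high group.
LOW_GROUP_MAX_HZ = 15.0

#: 1/f-ish default band variances; low frequencies dominate total power, so the
#: broadband mixture inherits low-frequency behaviour.
DEFAULT_BAND_POWERS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.5,
    "alpha": 0.35,
    "beta": 0.2,
    "gamma_low": 0.1,
    "gamma_high": 0.06,
    "gamma_very_high": 0.03,
}


@dataclass(frozen=True)
class CouplingStateModel:
    """Hidden Markov model over discrete coupling strengths in [-1, 1].

    The chain advances once per ``dwell_step_s`` seconds; the transition matrix
    is row-stochastic.  The generator realizes the first-order Markov
    assumption the downstream jump analysis rests on.
    """

    states: tuple[float, ...]
    transition_matrix: tuple[tuple[float, ...], ...]
    dwell_step_s: float

    def __post_init__(self) -> None:
        st = np.asarray(self.states, dtype=float)
        tm = np.asarray(self.transition_matrix, dtype=float)
        if st.ndim != 1 or st.size < 1:
            raise ValueError("states must be a nonempty 1-D sequence")
        if np.any(np.abs(st) > 1):
            raise ValueError("coupling strengths must lie in [-1, 1]")
        if tm.shape != (st.size, st.size):
            raise ValueError("transition_matrix must be square and match states")
        if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must be nonnegative and sum to 1")
        if not self.dwell_step_s > 0:
            raise ValueError("dwell_step_s must be > 0")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def states_array(self) -> np.ndarray:
        return np.asarray(self.states, dtype=float)

    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)

    def stationary_distribution(self) -> np.ndarray:
        tm = self.matrix()
        vals, vecs = np.linalg.eig(tm.T)
        idx = np.argmin(np.abs(vals - 1.0))
        if abs(vals[idx] - 1.0) > 1e-8:
            return np.full(self.n_states, 1.0 / self.n_states)
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        total = pi.sum()
        if total == 0 or not np.isfinite(total):
            return np.full(self.n_states, 1.0 / self.n_states)
        return pi / total

    def stationary_mean_coupling(self) -> float:
        return float(self.stationary_distribution() @ self.states_array())

    def sample_path(self, n_steps: int, rng: np.random.Generator) -> np.ndarray:
        """State *indices* of a stationary-start realization of the chain."""
        tm = self.matrix()
        pi = self.stationary_distribution()
        path = np.empty(n_steps, dtype=int)
        path[0] = rng.choice(self.n_states, p=pi)
        for t in range(1, n_steps):
            path[t] = rng.choice(self.n_states, p=tm[path[t - 1]])
        return path


def _random_walk_matrix(n: int, p_stay: float = 0.4) -> tuple[tuple[float, ...], ...]:
    tm = np.zeros((n, n))
    for i in range(n):
        moves = [j for j in (i - 1, i + 1) if 0 <= j < n]
        tm[i, i] = p_stay
        for j in moves:
            tm[i, j] = (1.0 - p_stay) / len(moves)
    return tuple(tuple(row) for row in tm)


#: Five well-separated positive coupling levels with nearest-neighbour
#: switching every 15 s: enough transitions in a 15 min run for the jump
#: statistics while keeping dwell times resolvable by a 60 s window.
DEFAULT_COUPLING_MODEL = CouplingStateModel(
    states=(0.1, 0.3, 0.5, 0.7, 0.9),
    transition_matrix=_random_walk_matrix(5),
    dwell_step_s=15.0,
)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    f_low: float,
    f_high: float,
    *,
    order: int = 4,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited with a zero-phase Butterworth."""
    white = rng.standard_normal(n_samples)
    nyq = fs / 2.0
    hi = min(f_high, 0.99 * nyq)
    sos = signal.butter(order, [f_low, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _coherence_kernel_sqrt(distances_mm: np.ndarray, fwhm_mm: float) -> np.ndarray:
    """Channel correlation matrix whose *square* is the target MSC kernel
    ``exp(-4 ln 2 (d / FWHM)^2)``.  Gaussian RBF matrices are positive definite."""
    if fwhm_mm <= 1e-9:
        return np.eye(distances_mm.shape[0])
    return np.exp(-2.0 * np.log(2.0) * (distances_mm / fwhm_mm) ** 2)


def _mixing_root(corr: np.ndarray) -> np.ndarray:
    n = corr.shape[0]
    return np.linalg.cholesky(corr + 1e-10 * np.eye(n))


def generate_lfp_grid(
    geometry: GridGeometry,
    duration_s: float,
    fs: float,
    band_powers: dict[str, float] | None = None,
    coherence_fwhm_mm: float | dict[str, float] = 1.2,
    seed: int = 0,
    *,
    bands: tuple[FrequencyBand, ...] = NARROW_BANDS,
) -> MultiChannelRecording:
    """Grid of channels summing band-limited Gaussian processes whose expected
    pairwise MSC in each band decays as a Gaussian of distance with the stated
    FWHM (per band when a mapping is given)."""
    _check_positive("duration_s", duration_s)
    _check_positive("fs", fs)
    max_edge = max(b.f_high for b in bands)
    if fs < 2.0 * max_edge:
        raise ValueError(f"fs={fs} Hz cannot represent bands up to {max_edge} Hz")
    if band_powers is None:
        band_powers = DEFAULT_BAND_POWERS
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    n_ch = geometry.n_channels
    dist = geometry.distance_matrix_mm()
    data = np.zeros((n_ch, n_samples))
    fwhm_by_band = {}
    for band in bands:
        power = band_powers.get(band.name, 0.0)
        if power <= 0:
            continue
        fwhm = (
            coherence_fwhm_mm[band.name]
            if isinstance(coherence_fwhm_mm, dict)
            else float(coherence_fwhm_mm)
        )
        fwhm_by_band[band.name] = fwhm
        root = _mixing_root(_coherence_kernel_sqrt(dist, fwhm))
        sources = np.vstack(
            [band_limited_noise(rng, n_samples, fs, band.f_low, band.f_high) for _ in range(n_ch)]
        )
        data += np.sqrt(power) * (root @ sources)
    return MultiChannelRecording(
        data,
        fs,
        geometry,
        {
            "generator": "lfp_grid",
            "seed": int(seed),
            "band_powers": dict(band_powers),
            "coherence_fwhm_mm": fwhm_by_band,
        },
    )


def band_fidelity(
    band: FrequencyBand, low_band_fidelity: float, high_band_fidelity: float
) -> float:
    """Low group (upper edge <= 15 Hz) takes the low fidelity, the rest the high."""
    return low_band_fidelity if band.f_high <= LOW_GROUP_MAX_HZ else high_band_fidelity


@dataclass
class CoupledPair:
    """Result of :func:`generate_coupled_pair`."""

    slow: VolumeSeries  # two columns: area_a, area_b
    fast_a: MultiChannelRecording
    fast_b: MultiChannelRecording
    coupling_per_volume: np.ndarray  # true coupling strength at each volume
    coupling_per_step: np.ndarray  # coupling strength at each Markov step
    state_path: np.ndarray  # state indices at each Markov step
    model: CouplingStateModel = field(repr=False, default=None)


def generate_coupled_pair(
    model: CouplingStateModel,
    duration_s: float,
    fs_fast: float,
    volume_interval_s: float,
    low_band_fidelity: float,
    high_band_fidelity: float,
    seed: int,
    *,
    bands: tuple[FrequencyBand, ...] = NARROW_BANDS,
    band_powers: dict[str, float] | None = None,
) -> CoupledPair:
    """Slow pair and fast pair sharing a hidden Markov coupling path.

    The slow signals are 0.01-0.1 Hz band-limited with instantaneous
    correlation equal to the coupling strength c(t).  Each fast band carries
    the path with its fidelity f: the band's target MSC is
    ``|f * c(t) + (1 - f) * c_bar|`` where c_bar is the stationary mean
    coupling, so fidelity 1 expresses the full dynamics and fidelity 0 a
    static coupling with no trace of the path.  The true path is returned for
    recovery tests.
    """
    for name, f in (("low_band_fidelity", low_band_fidelity), ("high_band_fidelity", high_band_fidelity)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    _check_positive("duration_s", duration_s)
    _check_positive("fs_fast", fs_fast)
    ratio = volume_interval_s * fs_fast
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("volume_interval_s must be an integer multiple of 1/fs_fast")
    if band_powers is None:
        band_powers = DEFAULT_BAND_POWERS

    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(duration_s / model.dwell_step_s))
    state_path = model.sample_path(n_steps, rng)
    c_step = model.states_array()[state_path]
    c_bar = model.stationary_mean_coupling()

    def path_at(times_s: np.ndarray) -> np.ndarray:
        idx = np.minimum((times_s / model.dwell_step_s).astype(int), n_steps - 1)
        return c_step[idx]

    # --- slow pair ---------------------------------------------------------
    fs_slow = 1.0 / volume_interval_s
    n_vol = int(round(duration_s / volume_interval_s))
    t_vol = (np.arange(n_vol) + 0.5) * volume_interval_s
    c_vol = path_at(t_vol)
    shared = band_limited_noise(rng, n_vol, fs_slow, *SLOW_BAND_HZ)
    noise_a = band_limited_noise(rng, n_vol, fs_slow, *SLOW_BAND_HZ)
    noise_b = band_limited_noise(rng, n_vol, fs_slow, *SLOW_BAND_HZ)
    w = np.sqrt(np.abs(c_vol))
    y_a = w * shared + np.sqrt(1.0 - np.abs(c_vol)) * noise_a
    y_b = np.sign(c_vol) * w * shared + np.sqrt(1.0 - np.abs(c_vol)) * noise_b
    slow = VolumeSeries(
        np.column_stack([y_a, y_b]),
        volume_interval_s,
        ["area_a", "area_b"],
        {"generator": "coupled_pair_slow", "seed": int(seed)},
    )

    # --- fast pair ---------------------------------------------------------
    n_fast = int(round(duration_s * fs_fast))
    t_fast = (np.arange(n_fast) + 0.5) / fs_fast
    c_fast = path_at(t_fast)
    x_a = np.zeros(n_fast)
    x_b = np.zeros(n_fast)
    fidelities = {}
    for band in bands:
        power = band_powers.get(band.name, 0.0)
        if power <= 0:
            continue
        f = band_fidelity(band, low_band_fidelity, high_band_fidelity)
        fidelities[band.name] = f
        target_msc = np.abs(f * c_fast + (1.0 - f) * c_bar)
        mix = np.sqrt(np.sqrt(target_msc))  # mixing weight w: MSC = w**4 ... see below
        # With x = w*s + sqrt(1-w^2)*n and unit-variance source/noise the band
        # coherence is w^4; choosing w = target^(1/4) yields MSC = target.
        s_b = band_limited_noise(rng, n_fast, fs_fast, band.f_low, band.f_high)
        n_a = band_limited_noise(rng, n_fast, fs_fast, band.f_low, band.f_high)
        n_b = band_limited_noise(rng, n_fast, fs_fast, band.f_low, band.f_high)
        amp = np.sqrt(power)
        resid = np.sqrt(np.clip(1.0 - mix**2, 0.0, None))
        x_a += amp * (mix * s_b + resid * n_a)
        x_b += amp * (mix * s_b + resid * n_b)
    meta = {
        "generator": "coupled_pair_fast",
        "seed": int(seed),
        "band_fidelities": fidelities,
        "band_powers": dict(band_powers),
    }
    fast_a = MultiChannelRecording(x_a[None, :], fs_fast, None, dict(meta, area="a"))
    fast_b = MultiChannelRecording(x_b[None, :], fs_fast, None, dict(meta, area="b"))
    return CoupledPair(slow, fast_a, fast_b, c_vol, c_step, state_path, model)


def generate_activation_map(
    grid_shape: tuple[int, int],
    center_mm: tuple[float, float],
    sigma_major_mm: float,
    sigma_minor_mm: float,
    orientation_rad: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    resolution_mm: float = 0.1,
) -> SpatialMap:
    """Unit-peak elliptical Gaussian blob plus optional white Gaussian noise.

    The orientation is the major-axis angle measured from the +col axis toward
    the +row axis; ground-truth parameters are recorded in the metadata.
    """
    for name, s in (("sigma_major_mm", sigma_major_mm), ("sigma_minor_mm", sigma_minor_mm)):
        if not s > 0:
            raise ValueError(f"{name} must be > 0, got {s}")
    n_rows, n_cols = grid_shape
    rr, cc = np.meshgrid(
        np.arange(n_rows) * resolution_mm, np.arange(n_cols) * resolution_mm, indexing="ij"
    )
    dr = rr - center_mm[0]
    dc = cc - center_mm[1]
    u = dc * np.cos(orientation_rad) + dr * np.sin(orientation_rad)
    v = -dc * np.sin(orientation_rad) + dr * np.cos(orientation_rad)
    values = np.exp(-(u**2 / (2 * sigma_major_mm**2) + v**2 / (2 * sigma_minor_mm**2)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return SpatialMap(
        values,
        resolution_mm,
        {
            "generator": "activation_map",
            "seed": int(seed),
            "true_center_mm": list(center_mm),
            "true_sigma_major_mm": sigma_major_mm,
            "true_sigma_minor_mm": sigma_minor_mm,
            "true_orientation_rad": orientation_rad,
            "noise_sd": noise_sd,
        },
    )


def generate_block_design_series(
    paradigm: StimulusParadigm,
    response_map: SpatialMap,
    *,
    fs: float | None = None,
    volume_interval_s: float | None = None,
    noise_sd: float = 0.0,
    baseline: float = 100.0,
    amplitude: float = 1.0,
    carrier_band: FrequencyBand | None = None,
    seed: int = 0,
) -> MultiChannelRecording | VolumeSeries:
    """Block-design run whose per-channel response is proportional to the map.

    Exactly one of ``fs`` (fast/LFP-like output) or ``volume_interval_s``
    (slow/volume output) must be given.

    * Slow: signal = baseline + amplitude*map * boxcar(on) + noise, so the
      noiseless percent change is ``100 * amplitude * map / baseline``.
    * Fast: band-limited carrier noise whose variance is multiplied by
      ``1 + amplitude*map`` during on-blocks, so the noiseless percent *power*
      change is ``100 * amplitude * map``.
    """
    if (fs is None) == (volume_interval_s is None):
        raise ValueError("give exactly one of fs or volume_interval_s")
    rng = np.random.default_rng(seed)
    amplitudes = amplitude * response_map.values.ravel()
    n_ch = amplitudes.size
    duration = paradigm.total_duration_s
    n_rows, n_cols = response_map.shape
    geometry = GridGeometry(n_rows, n_cols, response_map.resolution_mm)
    meta = {"generator": "block_design", "seed": int(seed), "paradigm": vars(paradigm)}

    if volume_interval_s is not None:
        if abs(paradigm.cycle_s / volume_interval_s - round(paradigm.cycle_s / volume_interval_s)) > 1e-9:
            raise ValueError("block durations must be commensurate with the volume interval")
        n_vol = int(round(duration / volume_interval_s))
        t = (np.arange(n_vol) + 0.5) * volume_interval_s
        on = paradigm.on_mask(t).astype(float)
        data = baseline + on[:, None] * amplitudes[None, :]
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        return VolumeSeries(
            data, volume_interval_s, [f"v{i}" for i in range(n_ch)], dict(meta, baseline=baseline)
        )

    if carrier_band is None:
        carrier_band = FrequencyBand("broadband", 1.0, 150.0)
    n_samples = int(round(duration * fs))
    t = (np.arange(n_samples) + 0.5) / fs
    on = paradigm.on_mask(t).astype(float)
    gain = np.sqrt(1.0 + np.clip(amplitudes[:, None] * on[None, :], -1.0, None))
    carrier = np.vstack(
        [
            band_limited_noise(rng, n_samples, fs, carrier_band.f_low, carrier_band.f_high)
            for _ in range(n_ch)
        ]
    )
    data = carrier * gain
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return MultiChannelRecording(data, fs, geometry, dict(meta, carrier_band=carrier_band.name))


def generate_stim_lfp_grid(
    geometry: GridGeometry,
    paradigm: StimulusParadigm,
    response_maps: dict[str, SpatialMap],
    fs: float,
    seed: int,
    *,
    bands: tuple[FrequencyBand, ...] = NARROW_BANDS,
    band_powers: dict[str, float] | None = None,
    amplitude: float = 1.0,
) -> MultiChannelRecording:
    """Stimulation-run grid recording with band-specific spatial response maps.

    Each narrow band contributes carrier noise at its default power whose
    variance rises by ``amplitude * map_b`` during on-blocks; summing the bands
    yields a single recording from which per-band percent-power-change maps can
    be measured.
    """
    if band_powers is None:
        band_powers = DEFAULT_BAND_POWERS
    rng = np.random.default_rng(seed)
    n_samples = int(round(paradigm.total_duration_s * fs))
    t = (np.arange(n_samples) + 0.5) / fs
    on = paradigm.on_mask(t).astype(float)
    n_ch = geometry.n_channels
    data = np.zeros((n_ch, n_samples))
    for band in bands:
        power = band_powers.get(band.name, 0.0)
        if power <= 0 or band.name not in response_maps:
            continue
        amps = amplitude * response_maps[band.name].values.ravel()
        if amps.size != n_ch:
            raise ValueError(f"response map for {band.name!r} does not match the grid")
        gain = np.sqrt(1.0 + np.clip(amps[:, None] * on[None, :], -1.0, None))
        carrier = np.vstack(
            [band_limited_noise(rng, n_samples, fs, band.f_low, band.f_high) for _ in range(n_ch)]
        )
        data += np.sqrt(power) * carrier * gain
    return MultiChannelRecording(
        data,
        fs,
        geometry,
        {"generator": "stim_lfp_grid", "seed": int(seed), "band_powers": dict(band_powers)},
    )
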