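"""End-to-end orchestration: generate -> filter -> connect -> window -> compare.

A *session* is one synthetic run; a *group* is ``n_runs`` sessions (default 9,
i.e. three runs from each of three synthetic animals) aggregated with paired
Wilcoxon signed-rank statistics.  Two experiments are wired up:

* **spatial**: per-band resting coherence maps and stimulus power-change maps
  on the electrode grid, each fitted with an elliptical-Gaussian PSF; the
  group table compares rest vs stimulation spatial extents per band.
* **dynamics**: a coupled region pair whose hidden Markov coupling path is
  expressed fully in the low-frequency bands and not at all in the high bands
  (configurable fidelities); sliding-window connectivity is discretized into
  states and modalities are compared through jump-ECDF K-S statistics, plus
  the Fourier decomposition of the windowed series.

All randomness flows from a single integer seed; rerunning a configuration
reproduces every output table byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .bands import BROADBAND, DEFAULT_BANDS, band_limited_power
from .bold import bandpass_slow
from .coherence import seed_coherence_map, stimulus_power_change_map
from .containers import GridGeometry, SpatialMap, StimulusParadigm
from .psf import FWHM_FACTOR, fit_elliptical_psf
from .states import jump_distribution, ks_two_sample
from .synth import (
    DEFAULT_BAND_POWERS,
    CouplingStateModel,
    band_fidelity,
    generate_coupled_pair,
    generate_lfp_grid,
    generate_stim_lfp_grid,
    _random_walk_matrix,
)
from .variation import variation_spectrum
from .windows import (
    MSC_DOMAIN,
    R_DOMAIN,
    bin_states,
    fisher_z,
    sliding_coherence_profiles,
    sliding_correlation,
)

__all__ = [
    "RunConfig",
    "REST_COHERENCE_FWHM_MM",
    "STIM_RESPONSE_FWHM_MM",
    "LOW_GROUP",
    "HIGH_GROUP",
    "wilcoxon_paired",
    "run_spatial_run",
    "run_dynamics_run",
    "run_session",
    "run_group",
]

#: Default resting-state MSC spatial-kernel FWHM per narrow band (mm).  Low
#: frequencies spread over a wider cortical neighbourhood than the gamma bands.
REST_COHERENCE_FWHM_MM: dict[str, float] = {
    "delta": 1.25,
    "theta": 1.45,
    "alpha": 1.40,
    "beta": 1.30,
    "gamma_low": 1.05,
    "gamma_high": 0.75,
    "gamma_very_high": 0.65,
}

#: Default stimulus-response spatial FWHM per narrow band (mm): roughly one
#: cortical column, slightly wider for the gamma-high response.
STIM_RESPONSE_FWHM_MM: dict[str, float] = {
    "delta": 1.20,
    "theta": 1.00,
    "alpha": 1.00,
    "beta": 1.00,
    "gamma_low": 1.00,
    "gamma_high": 1.05,
    "gamma_very_high": 1.00,
}

#: Band groups used in group-level direction tests (5-30 Hz vs 50-150 Hz).
LOW_GROUP = ("theta", "alpha", "beta")
HIGH_GROUP = ("gamma_high", "gamma_very_high")

#: Headline band pair for the dynamics comparison (delta vs gamma high).
HEADLINE_LOW_BAND = "delta"
HEADLINE_HIGH_BAND = "gamma_high"


@dataclass
class RunConfig:
    """Fully serializable configuration of a group run."""

    seed: int = 0
    out_dir: str = "dynfc_out"
    n_runs: int = 9
    # dynamics experiment
    duration_s: float = 900.0
    fs_fast: float = 500.0
    volume_interval_s: float = 3.0
    window_s: float = 60.0
    step_s: float = 3.0
    n_states: int = 50
    low_band_fidelity: float = 1.0
    high_band_fidelity: float = 0.0
    blp_smoothing_s: float = 0.5
    coupling_states: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    coupling_p_stay: float = 0.4
    dwell_step_s: float = 15.0
    bin_on_z: bool = False
    # spatial experiment
    grid_rows: int = 7
    grid_cols: int = 7
    spacing_mm: float = 0.4
    rest_duration_s: float = 120.0
    block_on_s: float = 30.0
    block_off_s: float = 30.0
    n_blocks: int = 7
    rest_coherence_fwhm_mm: dict = field(default_factory=lambda: dict(REST_COHERENCE_FWHM_MM))
    stim_response_fwhm_mm: dict = field(default_factory=lambda: dict(STIM_RESPONSE_FWHM_MM))
    stim_amplitude: float = 1.0
    do_spatial: bool = True
    do_dynamics: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for name in (
            "duration_s", "fs_fast", "volume_interval_s", "window_s", "step_s",
            "rest_duration_s", "block_on_s", "block_off_s", "spacing_mm", "dwell_step_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_runs", "n_states", "grid_rows", "grid_cols", "n_blocks"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("low_band_fidelity", "high_band_fidelity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.coupling_p_stay < 1.0:
            raise ValueError("coupling_p_stay must be in [0, 1)")
        if self.window_s > self.duration_s:
            raise ValueError("window_s cannot exceed duration_s")

    # -- derived objects ---------------------------------------------------
    def coupling_model(self) -> CouplingStateModel:
        return CouplingStateModel(
            states=tuple(self.coupling_states),
            transition_matrix=_random_walk_matrix(len(self.coupling_states), self.coupling_p_stay),
            dwell_step_s=self.dwell_step_s,
        )

    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols, self.spacing_mm)

    def paradigm(self) -> StimulusParadigm:
        return StimulusParadigm(self.block_on_s, self.block_off_s, self.n_blocks)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["coupling_states"] = list(d["coupling_states"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "coupling_states" in d:
            d["coupling_states"] = tuple(d["coupling_states"])
        return cls(**d)


def wilcoxon_paired(
    values_a, values_b, alternative: str = "two-sided"
) -> tuple[float, float, str]:
    """Paired Wilcoxon signed-rank test: (statistic, p, flag).

    Exact null distribution for n <= 25 without ties/zeros (scipy's automatic
    policy), normal approximation above.  All-zero differences are degenerate
    (p = 1); fewer than 5 pairs is flagged as insufficient for a p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0, "degenerate"
    if a.size < 5:
        return float(np.sum(diffs > 0)), float("nan"), "insufficient_n"
    res = stats.wilcoxon(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue), "ok"


# ---------------------------------------------------------------------------
# spatial experiment
# ---------------------------------------------------------------------------

def _stim_response_maps(config: RunConfig) -> dict[str, SpatialMap]:
    geom = config.geometry()
    center = (
        (geom.n_rows - 1) / 2.0 * geom.spacing_mm,
        (geom.n_cols - 1) / 2.0 * geom.spacing_mm,
    )
    coords_r, coords_c = np.meshgrid(
        np.arange(geom.n_rows) * geom.spacing_mm,
        np.arange(geom.n_cols) * geom.spacing_mm,
        indexing="ij",
    )
    maps = {}
    for name, fwhm in config.stim_response_fwhm_mm.items():
        sigma = fwhm / FWHM_FACTOR
        d2 = (coords_r - center[0]) ** 2 + (coords_c - center[1]) ** 2
        maps[name] = SpatialMap(
            np.exp(-d2 / (2 * sigma**2)), geom.spacing_mm, {"true_fwhm_mm": fwhm}
        )
    return maps


def run_spatial_run(config: RunConfig, seed: int, run_id: str = "run") -> pd.DataFrame:
    """One synthetic session of the spatial-extent experiment.

    Returns a tidy table with one row per band x condition carrying the fitted
    PSF parameters (FWHMs, half-maximum ellipse area).
    """
    rng = np.random.default_rng(seed)
    seed_rest = int(rng.integers(0, 2**31 - 1))
    seed_stim = int(rng.integers(0, 2**31 - 1))
    geom = config.geometry()
    paradigm = config.paradigm()

    rest_rec = generate_lfp_grid(
        geom,
        config.rest_duration_s,
        config.fs_fast,
        DEFAULT_BAND_POWERS,
        config.rest_coherence_fwhm_mm,
        seed_rest,
    )
    stim_rec = generate_stim_lfp_grid(
        geom,
        paradigm,
        _stim_response_maps(config),
        config.fs_fast,
        seed_stim,
        amplitude=config.stim_amplitude,
    )
    # seed electrode: the channel with the largest broadband stimulus response
    bb_map = stimulus_power_change_map(stim_rec, paradigm, BROADBAND)
    seed_ch = int(np.nanargmax(bb_map.values))

    rows = []
    for band in DEFAULT_BANDS:
        rest_map = seed_coherence_map(rest_rec, seed_ch, band).values
        stim_map = stimulus_power_change_map(stim_rec, paradigm, band)
        for condition, smap in (("rest", rest_map), ("stim", stim_map)):
            fit = fit_elliptical_psf(smap, major_axis_direction_rad=0.0)
            rows.append(
                {
                    "run_id": run_id,
                    "band": band.name,
                    "condition": condition,
                    "fwhm_major_mm": fit.fwhm_major_mm,
                    "fwhm_minor_mm": fit.fwhm_minor_mm,
                    "area_mm2": fit.area_mm2,
                    "center_row_mm": fit.center_mm[0],
                    "center_col_mm": fit.center_mm[1],
                    "goodness": fit.goodness,
                    "seed_channel": seed_ch,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamics experiment
# ---------------------------------------------------------------------------

def _downsample_to_volumes(x: np.ndarray, fs: float, volume_interval_s: float) -> np.ndarray:
    per_vol = int(round(volume_interval_s * fs))
    n_vol = x.size // per_vol
    return x[: n_vol * per_vol].reshape(n_vol, per_vol).mean(axis=1)


def run_dynamics_run(config: RunConfig, seed: int, run_id: str = "run") -> dict:
    """One synthetic session of the temporal-dynamics experiment.

    Returns ``{"ks": DataFrame, "variation": DataFrame, "windowed": dict,
    "pair": CoupledPair}``.  The K-S table holds one row per band for the
    coherence-based and BLP-correlation-based fast sequences versus the slow
    (hemodynamic-like) correlation sequence.
    """
    model = config.coupling_model()
    pair = generate_coupled_pair(
        model,
        config.duration_s,
        config.fs_fast,
        config.volume_interval_s,
        config.low_band_fidelity,
        config.high_band_fidelity,
        seed,
    )
    slow = bandpass_slow(pair.slow)
    wc_slow = sliding_correlation(
        slow.data[:, 0], slow.data[:, 1], config.window_s, config.step_s,
        config.volume_interval_s,
    )
    r_domain = R_DOMAIN
    slow_values = fisher_z(wc_slow.values) if config.bin_on_z else wc_slow.values
    slow_states = bin_states(slow_values, config.n_states, r_domain)

    coh = sliding_coherence_profiles(
        pair.fast_a.data[0], pair.fast_b.data[0], config.fs_fast, DEFAULT_BANDS,
        config.window_s, config.step_s,
    )

    ks_rows = []
    variation_rows = []
    windowed = {"slow_r": wc_slow}
    slow_jumps = jump_distribution(slow_states)

    spec_slow = variation_spectrum(wc_slow)
    variation_rows.append(
        {"run_id": run_id, "modality": "slow_r", "band": "", **spec_slow.cumulative_bands}
    )

    for band in DEFAULT_BANDS:
        wc_band = coh[band.name]
        windowed[f"coherence_{band.name}"] = wc_band
        band_states = bin_states(wc_band, config.n_states, MSC_DOMAIN)
        ks = ks_two_sample(
            slow_jumps, jump_distribution(band_states),
            pair=("slow_r", band.name), band=band, measure="coherence",
        )
        fid = band_fidelity(band, config.low_band_fidelity, config.high_band_fidelity)
        ks_rows.append(
            {
                "run_id": run_id,
                "band": band.name,
                "measure": "coherence",
                "ks_statistic": ks.statistic,
                "fidelity": fid,
            }
        )
        spec_band = variation_spectrum(wc_band)
        variation_rows.append(
            {
                "run_id": run_id,
                "modality": "coherence",
                "band": band.name,
                **spec_band.cumulative_bands,
            }
        )

        # band-limited power correlation route
        env_a = band_limited_power(pair.fast_a, band, config.blp_smoothing_s).data[0]
        env_b = band_limited_power(pair.fast_b, band, config.blp_smoothing_s).data[0]
        blp_a = _downsample_to_volumes(env_a, config.fs_fast, config.volume_interval_s)
        blp_b = _downsample_to_volumes(env_b, config.fs_fast, config.volume_interval_s)
        wc_blp = sliding_correlation(
            blp_a, blp_b, config.window_s, config.step_s, config.volume_interval_s,
            measure="blp_r",
        )
        windowed[f"blp_{band.name}"] = wc_blp
        blp_values = fisher_z(wc_blp.values) if config.bin_on_z else wc_blp.values
        blp_states = bin_states(blp_values, config.n_states, r_domain)
        ks_blp = ks_two_sample(
            slow_jumps, jump_distribution(blp_states),
            pair=("slow_r", band.name), band=band, measure="blp",
        )
        ks_rows.append(
            {
                "run_id": run_id,
                "band": band.name,
                "measure": "blp",
                "ks_statistic": ks_blp.statistic,
                "fidelity": fid,
            }
        )

    return {
        "ks": pd.DataFrame(ks_rows),
        "variation": pd.DataFrame(variation_rows),
        "windowed": windowed,
        "pair": pair,
    }


# ---------------------------------------------------------------------------
# sessions and groups
# ---------------------------------------------------------------------------

def _write_windowed_csv(path: Path, windowed: dict) -> None:
    frames = []
    for name, wc in windowed.items():
        frames.append(
            pd.DataFrame(
                {
                    "series": name,
                    "window_start_s": wc.window_starts_s(),
                    "value": wc.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def run_session(config: RunConfig, seed: int, run_id: str, out_dir: Path | None = None) -> dict:
    """Run one session (spatial and/or dynamics) and optionally persist artifacts."""
    results: dict = {"run_id": run_id, "seed": seed}
    if config.do_spatial:
        results["psf"] = run_spatial_run(config, seed, run_id)
    if config.do_dynamics:
        dyn = run_dynamics_run(config, seed, run_id)
        results["ks"] = dyn["ks"]
        results["variation"] = dyn["variation"]
        results["windowed"] = dyn["windowed"]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if "psf" in results:
            results["psf"].to_csv(out_dir / "psf_fits.csv", index=False)
        if "ks" in results:
            results["ks"].to_csv(out_dir / "ks_results.csv", index=False)
            results["variation"].to_csv(out_dir / "variation_bands.csv", index=False)
            _write_windowed_csv(out_dir / "windowed_connectivity.csv", results["windowed"])
    return results


def _group_comparisons(psf: pd.DataFrame | None, ks: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    if psf is not None and len(psf):
        wide = psf.pivot_table(
            index=["run_id", "band"], columns="condition", values="area_mm2"
        ).reset_index()
        for band in sorted(wide["band"].unique()):
            sel = wide[wide["band"] == band]
            rest, stim = sel["rest"].to_numpy(), sel["stim"].to_numpy()
            direction = "rest_gt_stim" if np.median(rest - stim) > 0 else "stim_gt_rest"
            alt = "greater" if direction == "rest_gt_stim" else "less"
            stat, p, flag = wilcoxon_paired(rest, stim, alternative=alt)
            rows.append(
                {
                    "comparison": "psf_area_rest_vs_stim",
                    "band": band,
                    "measure": "area_mm2",
                    "direction": direction,
                    "n_consistent_runs": int(np.sum((rest - stim > 0) == (np.median(rest - stim) > 0))),
                    "n_runs": len(sel),
                    "statistic": stat,
                    "p_value": p,
                    "flag": flag,
                }
            )
    if ks is not None and len(ks):
        for measure in sorted(ks["measure"].unique()):
            sub = ks[ks["measure"] == measure]
            low = sub[sub["band"] == HEADLINE_LOW_BAND].sort_values("run_id")["ks_statistic"]
            high = sub[sub["band"] == HEADLINE_HIGH_BAND].sort_values("run_id")["ks_statistic"]
            low, high = low.to_numpy(), high.to_numpy()
            stat, p, flag = wilcoxon_paired(low, high, alternative="less")
            rows.append(
                {
                    "comparison": f"ks_{HEADLINE_LOW_BAND}_vs_{HEADLINE_HIGH_BAND}",
                    "band": f"{HEADLINE_LOW_BAND}|{HEADLINE_HIGH_BAND}",
                    "measure": measure,
                    "direction": "low_lt_high",
                    "n_consistent_runs": int(np.sum(low < high)),
                    "n_runs": low.size,
                    "statistic": stat,
                    "p_value": p,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def run_group(config: RunConfig, out_dir: Path | str | None = None) -> dict:
    """Run ``config.n_runs`` sessions and aggregate group tables.

    Sub-seeds for the individual runs are drawn deterministically from the
    configured master seed, so the whole group is reproducible end to end.
    """
    rng = np.random.default_rng(config.seed)
    run_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=config.n_runs)]
    out_path = Path(out_dir) if out_dir is not None else None

    psf_frames, ks_frames, var_frames = [], [], []
    for k, run_seed in enumerate(run_seeds):
        run_id = f"run{k:02d}"
        run_out = out_path / run_id if out_path is not None else None
        res = run_session(config, run_seed, run_id, run_out)
        if "psf" in res:
            psf_frames.append(res["psf"])
        if "ks" in res:
            ks_frames.append(res["ks"])
            var_frames.append(res["variation"])

    psf = pd.concat(psf_frames, ignore_index=True) if psf_frames else None
    ks = pd.concat(ks_frames, ignore_index=True) if ks_frames else None
    variation = pd.concat(var_frames, ignore_index=True) if var_frames else None
    comparisons = _group_comparisons(psf, ks)

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        manifest = {"run_seeds": run_seeds, "artifacts": []}
        for name, df in (
            ("psf_fits.csv", psf),
            ("ks_results.csv", ks),
            ("variation_bands.csv", variation),
            ("group_comparisons.csv", comparisons),
        ):
            if df is not None:
                df.to_csv(out_path / name, index=False)
                manifest["artifacts"].append(name)
        config.to_yaml(out_path / "config.yaml")
        manifest["artifacts"].append("config.yaml")
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "psf": psf,
        "ks": ks,
        "variation": variation,
        "comparisons": comparisons,
        "run_seeds": run_seeds,
    }
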