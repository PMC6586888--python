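"""Core data containers shared by every analysis stage.

Conventions
-----------
* Grids are row-major with the origin at the top-left electrode/voxel;
  physical coordinates are millimetres.
* Multichannel fast recordings are ``(n_channels, n_samples)`` float arrays
  with a sampling rate in Hz.
* Slow (volume-by-volume) series are ``(n_volumes, n_series)`` arrays with a
  fixed volume interval in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "GridGeometry",
    "MultiChannelRecording",
    "VolumeSeries",
    "SpatialMap",
    "StimulusParadigm",
]


@dataclass(frozen=True)
class GridGeometry:
    """Rectangular recording grid (e.g. a 7x7 microelectrode array at 0.4 mm pitch)."""

    n_rows: int
    n_cols: int
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.n_cols < 1:
            raise ValueError(f"n_cols must be >= 1, got {self.n_cols}")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def coordinates_mm(self) -> np.ndarray:
        """(n_channels, 2) array of (row_mm, col_mm) positions, row-major order."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([rows, cols]).astype(float) * self.spacing_mm

    def distance_matrix_mm(self) -> np.ndarray:
        xy = self.coordinates_mm()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def channel_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"(row, col)=({row}, {col}) outside {self.shape} grid")
        return row * self.n_cols + col


@dataclass
class MultiChannelRecording:
    """Electrode-grid time series: ``data`` is (n_channels, n_samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    geometry: GridGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.geometry is not None and self.data.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but geometry expects "
                f"{self.geometry.n_channels}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=self.data)
            d.attrs["fs"] = self.fs
            if self.geometry is not None:
                d.attrs["n_rows"] = self.geometry.n_rows
                d.attrs["n_cols"] = self.geometry.n_cols
                d.attrs["spacing_mm"] = self.geometry.spacing_mm
            f.attrs["meta_json"] = json.dumps(self.meta, sort_keys=True, default=float)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "MultiChannelRecording":
        with h5py.File(path, "r") as f:
            d = f["data"]
            geometry = None
            if "n_rows" in d.attrs:
                geometry = GridGeometry(
                    int(d.attrs["n_rows"]), int(d.attrs["n_cols"]), float(d.attrs["spacing_mm"])
                )
            meta = json.loads(f.attrs.get("meta_json", "{}"))
            return cls(d[...], float(d.attrs["fs"]), geometry, meta)


@dataclass
class VolumeSeries:
    """Slow voxel/ROI time series sampled once per imaging volume."""

    data: np.ndarray
    volume_interval_s: float
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if not self.volume_interval_s > 0:
            raise ValueError(f"volume_interval_s must be > 0, got {self.volume_interval_s}")
        if self.labels is None:
            self.labels = [f"s{i}" for i in range(self.data.shape[1])]
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("labels length must match the number of series")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def fs(self) -> float:
        return 1.0 / self.volume_interval_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.volume_interval_s

    def series(self, label: str) -> np.ndarray:
        return self.data[:, self.labels.index(label)]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.data, columns=self.labels).to_csv(path, index=False)
        sidecar = {"volume_interval_s": self.volume_interval_s, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "VolumeSeries":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            df.to_numpy(),
            float(sidecar["volume_interval_s"]),
            list(df.columns),
            sidecar.get("meta", {}),
        )


@dataclass
class SpatialMap:
    """2-D scalar field (activation %, correlation or coherence) on a square-pixel grid."""

    values: np.ndarray
    resolution_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.resolution_mm > 0:
            raise ValueError(f"resolution_mm must be > 0, got {self.resolution_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def extent_mm(self) -> tuple[float, float]:
        """(row extent, col extent) spanned by pixel centres."""
        return (
            (self.shape[0] - 1) * self.resolution_mm,
            (self.shape[1] - 1) * self.resolution_mm,
        )

    def normalized(self) -> "SpatialMap":
        """Map scaled so its maximum finite value is 1."""
        vmax = np.nanmax(self.values)
        if not np.isfinite(vmax) or vmax == 0:
            raise ValueError("cannot normalize a map whose maximum is zero or non-finite")
        return SpatialMap(self.values / vmax, self.resolution_mm, dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        sidecar = {"resolution_mm": self.resolution_mm, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpatialMap":
        path = Path(path)
        values = np.loadtxt(path, delimiter=",")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(values, float(sidecar["resolution_mm"]), sidecar.get("meta", {}))


@dataclass(frozen=True)
class StimulusParadigm:
    """Block design: each block is ``block_off_s`` of rest followed by ``block_on_s``
    of stimulation at ``rate_hz`` (e.g. 30 s off / 30 s on, 8 Hz vibrotactile)."""

    block_on_s: float = 30.0
    block_off_s: float = 30.0
    n_blocks: int = 7
    rate_hz: float = 8.0

    def __post_init__(self) -> None:
        for name in ("block_on_s", "block_off_s", "rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")

    @property
    def cycle_s(self) -> float:
        return self.block_on_s + self.block_off_s

    @property
    def total_duration_s(self) -> float:
        return self.n_blocks * self.cycle_s

    def on_intervals_s(self) -> list[tuple[float, float]]:
        """(start, end) of every on-block; the run begins with an off (baseline) period."""
        return [
            (k * self.cycle_s + self.block_off_s, (k + 1) * self.cycle_s)
            for k in range(self.n_blocks)
        ]

    def on_mask(self, times_s: np.ndarray) -> np.ndarray:
        times_s = np.asarray(times_s, dtype=float)
        phase = np.mod(times_s, self.cycle_s)
        in_run = times_s < self.total_duration_s
        return in_run & (phase >= self.block_off_s)
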