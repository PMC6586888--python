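"""Single-step jump distributions of discretized connectivity and their
two-sample Kolmogorov-Smirnov comparison.

The instantaneous degree of connectivity is treated as a brain state; the
empirical CDF of signed single-step jumps ``state[t+1] - state[t]`` summarizes
the transition dynamics (a first-order Markov view: only the present state
conditions the next).  The two-sample K-S statistic
``sup_v |F_a(v) - F_b(v)|`` over the union of observed jump values is used as
a distance between modalities: lower means more similar dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import FrequencyBand
from .windows import StateSequence

__all__ = [
    "JumpDistribution",
    "KsResult",
    "jump_distribution",
    "ks_two_sample",
    "ks_band_profile",
    "transition_matrix",
    "transition_matrix_distance",
]


@dataclass
class JumpDistribution:
    """Signed single-step state jumps and their empirical CDF."""

    jumps: np.ndarray
    n_missing_transitions: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.jumps = np.sort(np.asarray(self.jumps, dtype=int).ravel())

    @property
    def n(self) -> int:
        return self.jumps.size

    def ecdf(self, values) -> np.ndarray:
        """Right-continuous ECDF evaluated at ``values``."""
        values = np.asarray(values)
        return np.searchsorted(self.jumps, values, side="right") / self.n


@dataclass
class KsResult:
    statistic: float
    pair: tuple[str, str]
    band: FrequencyBand | None = None
    measure: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError(f"K-S statistic must be in [0, 1], got {self.statistic}")


def jump_distribution(seq: StateSequence, *, absolute: bool = False) -> JumpDistribution:
    """Signed (default) single-step differences of a state sequence.

    Missing states break transitions: no jump is counted across a gap, and the
    number of dropped transitions is recorded.  ``absolute=True`` switches to
    |jump| magnitudes (sensitivity variant).
    """
    if len(seq) < 2:
        raise ValueError("need a state sequence of length >= 2")
    ok = ~seq.missing
    valid_pair = ok[:-1] & ok[1:]
    if not valid_pair.any():
        raise ValueError("no valid single-step transition (all states missing)")
    diffs = (seq.states[1:] - seq.states[:-1])[valid_pair]
    if absolute:
        diffs = np.abs(diffs)
    n_dropped = int((~valid_pair).sum())
    return JumpDistribution(diffs, n_dropped, {"absolute": absolute})


def ks_two_sample(
    a: JumpDistribution,
    b: JumpDistribution,
    *,
    pair: tuple[str, str] = ("a", "b"),
    band: FrequencyBand | None = None,
    measure: str | None = None,
) -> KsResult:
    """sup over the union of observed jump values of |ECDF_a - ECDF_b|."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both jump distributions must be nonempty")
    grid = np.union1d(a.jumps, b.jumps)
    d = float(np.max(np.abs(a.ecdf(grid) - b.ecdf(grid))))
    return KsResult(d, pair, band, measure)


def ks_band_profile(
    slow_seq: StateSequence,
    fast_seqs: dict[str, StateSequence],
    *,
    bands: dict[str, FrequencyBand] | None = None,
    measure: str = "coherence",
    slow_label: str = "slow",
) -> list[KsResult]:
    """One K-S statistic per band between the slow-modality jump ECDF and each
    fast-modality (per-band) jump ECDF."""
    slow_jumps = jump_distribution(slow_seq)
    results = []
    for name, seq in fast_seqs.items():
        fast_jumps = jump_distribution(seq)
        band = bands.get(name) if bands else None
        results.append(
            ks_two_sample(
                slow_jumps, fast_jumps, pair=(slow_label, name), band=band, measure=measure
            )
        )
    return results


def transition_matrix(seq: StateSequence) -> np.ndarray:
    """Row-normalized empirical transition-count matrix (diagnostic; the
    headline comparison uses jump ECDFs)."""
    n = seq.n_states
    counts = np.zeros((n, n))
    ok = ~seq.missing
    for s0, s1, v in zip(seq.states[:-1], seq.states[1:], ok[:-1] & ok[1:]):
        if v:
            counts[s0 - 1, s1 - 1] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1), 0.0)
    return probs


def transition_matrix_distance(a: StateSequence, b: StateSequence) -> float:
    """Frobenius distance between empirical transition matrices (diagnostic)."""
    return float(np.linalg.norm(transition_matrix(a) - transition_matrix(b)))
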