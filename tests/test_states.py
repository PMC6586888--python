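import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dynfc import jump_distribution, ks_band_profile, ks_two_sample
from dynfc.states import JumpDistribution, transition_matrix, transition_matrix_distance
from dynfc.windows import StateSequence


def seq(states, n_states=50, missing=None):
    return StateSequence(np.asarray(states), n_states, (-1.0, 1.0), missing)


def brute_force_ks(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle: double loop over every observed jump value."""
    best = 0.0
    for v in set(a.tolist()) | set(b.tolist()):
        fa = np.sum(a <= v) / a.size
        fb = np.sum(b <= v) / b.size
        best = max(best, abs(fa - fb))
    return best


class TestJumpDistribution:
    def test_constant_sequence_unit_step_at_zero(self):
        jd = jump_distribution(seq([7] * 5))
        assert np.all(jd.jumps == 0)
        assert jd.ecdf([-1, 0, 1]).tolist() == [0.0, 1.0, 1.0]

    def test_enumerated_example_1_2_1(self):
        jd = jump_distribution(seq([1, 2, 1]))
        assert sorted(jd.jumps.tolist()) == [-1, 1]
        assert jd.ecdf(-1) == 0.5
        assert jd.ecdf(1) == 1.0

    def test_strictly_increasing_sequence(self):
        jd = jump_distribution(seq(list(range(1, 11))))
        assert jd.n == 9
        assert np.all(jd.jumps == 1)

    def test_missing_states_break_transitions(self):
        missing = np.array([False, True, False, False])
        jd = jump_distribution(seq([1, 1, 5, 6], missing=missing))
        # transitions 1->1 and 1->5 involve the masked element and are dropped
        assert jd.jumps.tolist() == [1]
        assert jd.n_missing_transitions == 2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            jump_distribution(seq([1, 2, 3], missing=np.array([True, True, True])))

    def test_absolute_variant(self):
        jd = jump_distribution(seq([3, 1, 3]), absolute=True)
        assert jd.jumps.tolist() == [2, 2]


class TestKsTwoSample:
    def test_worked_example_one_third(self):
        a = JumpDistribution(np.array([0, 0, 1]))
        b = JumpDistribution(np.array([0, 1, 1]))
        assert ks_two_sample(a, b).statistic == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_identical_multisets_give_zero(self):
        a = JumpDistribution(np.array([0, -2, 5, 5]))
        b = JumpDistribution(np.array([5, 0, 5, -2]))
        assert ks_two_sample(a, b).statistic == 0.0

    def test_disjoint_supports_give_one(self):
        a = JumpDistribution(np.full(4, -2))
        b = JumpDistribution(np.full(6, 2))
        assert ks_two_sample(a, b).statistic == 1.0

    def test_symmetry_exact(self, rng):
        a = JumpDistribution(rng.integers(-5, 6, 40))
        b = JumpDistribution(rng.integers(-5, 6, 25))
        assert ks_two_sample(a, b).statistic == ks_two_sample(b, a).statistic

    @given(
        st.lists(st.integers(1, 50), min_size=2, max_size=50),
        st.lists(st.integers(1, 50), min_size=2, max_size=50),
    )
    def test_matches_brute_force_and_scipy(self, states_a, states_b):
        ja = jump_distribution(seq(states_a))
        jb = jump_distribution(seq(states_b))
        d = ks_two_sample(ja, jb).statistic
        assert d == brute_force_ks(ja.jumps, jb.jumps)
        assert d == pytest.approx(sps.ks_2samp(ja.jumps, jb.jumps).statistic, abs=1e-12)
        assert 0.0 <= d <= 1.0


class TestKsBandProfile:
    def test_self_comparison_gives_all_zero(self):
        s = seq([1, 5, 3, 8, 2, 2, 9])
        results = ks_band_profile(s, {"delta": s, "gamma_high": s})
        assert all(r.statistic == 0.0 for r in results)

    def test_band_order_permutation_permutes_outputs(self, rng):
        s = seq(rng.integers(1, 51, 60))
        fast = {name: seq(rng.integers(1, 51, 60)) for name in ("a", "b", "c")}
        res1 = {r.pair[1]: r.statistic for r in ks_band_profile(s, fast)}
        reordered = {k: fast[k] for k in ("c", "a", "b")}
        res2 = {r.pair[1]: r.statistic for r in ks_band_profile(s, reordered)}
        assert res1 == res2


class TestDirectionalRecovery:
    def test_mean_ks_nondecreasing_as_fidelity_falls(self):
        """Over the fidelity sweep 1 -> 0.5 -> 0, the delta-band coherence jump
        ECDF drifts away from the slow modality's: mean K-S is monotone
        nondecreasing (sign test over seeds)."""
        from dynfc import bandpass_slow, band_by_name, bin_states, sliding_correlation
        from dynfc.states import jump_distribution as jd, ks_two_sample as ks
        from dynfc.synth import DEFAULT_COUPLING_MODEL, generate_coupled_pair
        from dynfc.windows import MSC_DOMAIN, R_DOMAIN, sliding_band_coherence

        delta = band_by_name("delta")
        per_fid = {}
        for fid in (1.0, 0.5, 0.0):
            stats = []
            for seed in range(10):
                pair = generate_coupled_pair(
                    DEFAULT_COUPLING_MODEL, 900.0, 500.0, 3.0, fid, fid, seed=seed
                )
                slow = bandpass_slow(pair.slow)
                wc_slow = sliding_correlation(slow.data[:, 0], slow.data[:, 1], 60.0, 3.0, 3.0)
                wc_fast = sliding_band_coherence(
                    pair.fast_a.data[0], pair.fast_b.data[0], 500.0, delta, 60.0, 3.0
                )
                stats.append(
                    ks(
                        jd(bin_states(wc_slow, 50, R_DOMAIN)),
                        jd(bin_states(wc_fast, 50, MSC_DOMAIN)),
                    ).statistic
                )
            per_fid[fid] = np.array(stats)
        means = [per_fid[f].mean() for f in (1.0, 0.5, 0.0)]
        assert means[0] <= means[1] <= means[2]
        # endpoint sign test: nearly every seed moves in the expected direction
        assert np.sum(per_fid[0.0] > per_fid[1.0]) >= 9


class TestTransitionMatrixDiagnostics:
    def test_rows_are_stochastic_where_visited(self):
        tm = transition_matrix(seq([1, 2, 1, 2, 3], n_states=3))
        sums = tm.sum(axis=1)
        visited = sums > 0
        np.testing.assert_allclose(sums[visited], 1.0)

    def test_distance_zero_for_identical_sequences(self):
        s = seq([1, 2, 3, 2, 1], n_states=3)
        assert transition_matrix_distance(s, s) == 0.0
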