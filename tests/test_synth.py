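import numpy as np
import pytest

from dynfc import (
    GridGeometry,
    SpatialMap,
    StimulusParadigm,
    band_average_msc,
    band_by_name,
    msc,
    sliding_correlation,
)
from dynfc.bands import FrequencyBand
from dynfc.psf import FWHM_FACTOR
from dynfc.synth import (
    DEFAULT_COUPLING_MODEL,
    CouplingStateModel,
    _random_walk_matrix,
    generate_activation_map,
    generate_block_design_series,
    generate_coupled_pair,
    generate_lfp_grid,
)

ALPHA = band_by_name("alpha")


class TestCouplingStateModel:
    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CouplingStateModel((0.1, 0.9), ((0.5, 0.4), (0.0, 1.0)), 15.0)

    def test_coupling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            CouplingStateModel((0.5, 1.5), _random_walk_matrix(2), 15.0)

    def test_stationary_distribution_of_random_walk(self):
        pi = DEFAULT_COUPLING_MODEL.stationary_distribution()
        np.testing.assert_allclose(pi @ DEFAULT_COUPLING_MODEL.matrix(), pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_identity_matrix_keeps_path_constant(self):
        model = CouplingStateModel((0.2, 0.8), ((1.0, 0.0), (0.0, 1.0)), 15.0)
        path = model.sample_path(50, np.random.default_rng(0))
        assert len(np.unique(path)) == 1


class TestLfpGrid:
    def test_deterministic_given_seed(self):
        geom = GridGeometry(2, 2, 0.4)
        a = generate_lfp_grid(geom, 5.0, 500.0, {"alpha": 1.0}, 1.2, seed=7, bands=(ALPHA,))
        b = generate_lfp_grid(geom, 5.0, 500.0, {"alpha": 1.0}, 1.2, seed=7, bands=(ALPHA,))
        np.testing.assert_array_equal(a.data, b.data)

    def test_nonpositive_duration_rejected_with_field_name(self):
        with pytest.raises(ValueError, match="duration_s"):
            generate_lfp_grid(GridGeometry(2, 2, 0.4), -1.0, 500.0, seed=0)

    def test_fs_below_twice_band_edge_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|represent"):
            generate_lfp_grid(GridGeometry(2, 2, 0.4), 5.0, 200.0, seed=0)

    def test_zero_width_kernel_gives_bias_floor_coherence(self):
        geom = GridGeometry(1, 2, 0.4)
        rec = generate_lfp_grid(geom, 130.0, 500.0, {"alpha": 1.0}, 0.0, seed=1, bands=(ALPHA,))
        spec = msc(rec.data[0], rec.data[1], 500.0)
        level = band_average_msc(spec, ALPHA)
        assert level < 3.0 / spec.n_averages  # independent channels: only estimator bias

    def test_coincident_channels_fully_coherent(self):
        geom = GridGeometry(1, 2, 1e-9)  # effectively the same location
        rec = generate_lfp_grid(geom, 130.0, 500.0, {"alpha": 1.0}, 1.2, seed=1, bands=(ALPHA,))
        spec = msc(rec.data[0], rec.data[1], 500.0)
        assert band_average_msc(spec, ALPHA) > 0.99

    def test_kernel_calibration_at_half_width(self):
        # FWHM 1.2 mm at distance 0.6 mm: MSC = exp(-4 ln2 (0.6/1.2)^2) = 0.5
        geom = GridGeometry(1, 2, 0.6)
        rec = generate_lfp_grid(geom, 130.0, 500.0, {"alpha": 1.0}, 1.2, seed=2, bands=(ALPHA,))
        spec = msc(rec.data[0], rec.data[1], 500.0)
        assert spec.n_averages >= 60
        assert band_average_msc(spec, ALPHA) == pytest.approx(0.5, abs=0.1)


class TestCoupledPair:
    def test_deterministic_given_seed(self):
        kw = dict(duration_s=120.0, fs_fast=500.0, volume_interval_s=3.0)
        a = generate_coupled_pair(DEFAULT_COUPLING_MODEL, seed=9, low_band_fidelity=1.0, high_band_fidelity=0.0, **kw)
        b = generate_coupled_pair(DEFAULT_COUPLING_MODEL, seed=9, low_band_fidelity=1.0, high_band_fidelity=0.0, **kw)
        np.testing.assert_array_equal(a.slow.data, b.slow.data)
        np.testing.assert_array_equal(a.fast_a.data, b.fast_a.data)
        np.testing.assert_array_equal(a.state_path, b.state_path)

    def test_invalid_fidelity_rejected(self):
        with pytest.raises(ValueError, match="fidelity"):
            generate_coupled_pair(DEFAULT_COUPLING_MODEL, 120.0, 500.0, 3.0, 1.5, 0.0, seed=0)

    def test_incommensurate_volume_interval_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            generate_coupled_pair(DEFAULT_COUPLING_MODEL, 120.0, 500.0, 3.0001, 1.0, 0.0, seed=0)

    def test_constant_path_leaves_only_estimator_noise(self):
        model = CouplingStateModel((0.6,), ((1.0,),), 15.0)
        pair = generate_coupled_pair(model, 900.0, 500.0, 3.0, 1.0, 1.0, seed=4)
        wc = sliding_correlation(pair.slow.data[:, 0], pair.slow.data[:, 1], 60.0, 3.0, 3.0)
        assert np.all(pair.coupling_per_volume == 0.6)
        # windowed variance is estimator noise only: small compared with the
        # state spread a dynamic path would produce
        assert np.nanstd(wc.values) < 0.25
        assert np.nanmean(wc.values) == pytest.approx(0.6, abs=0.15)

    def test_state_path_recovery_with_slow_switching(self):
        """With full fidelity and dwell >= 2x window, windowed slow-signal
        correlation tracks the true coupling path at rho >= 0.8."""
        model = CouplingStateModel((0.05, 0.95), _random_walk_matrix(2, 0.5), 120.0)
        for seed in (0, 1, 2):
            pair = generate_coupled_pair(model, 1800.0, 500.0, 3.0, 1.0, 0.0, seed=seed)
            wc = sliding_correlation(pair.slow.data[:, 0], pair.slow.data[:, 1], 60.0, 3.0, 3.0)
            c = pair.coupling_per_volume
            w = 20
            truth = np.array([c[k : k + w].mean() for k in range(wc.n_windows)])
            rho = np.corrcoef(wc.values, truth)[0, 1]
            assert rho >= 0.8

    def test_slow_series_spectral_content_in_band(self):
        pair = generate_coupled_pair(DEFAULT_COUPLING_MODEL, 900.0, 500.0, 3.0, 1.0, 0.0, seed=6)
        x = pair.slow.data[:, 0]
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(x.size, d=3.0)
        out_of_band = spec[freqs > 0.12].sum() / spec.sum()
        assert out_of_band < 0.05


class TestActivationMap:
    def test_noiseless_peak_at_center(self):
        m = generate_activation_map((41, 41), (2.0, 2.0), 1.0, 0.5, 0.0, 0.0, seed=0)
        assert m.values.max() == pytest.approx(1.0)
        assert np.unravel_index(np.argmax(m.values), m.shape) == (20, 20)

    def test_ground_truth_fwhm_metadata(self):
        m = generate_activation_map((41, 41), (2.0, 2.0), 1.0, 0.5, 0.0, 0.0, seed=0)
        assert FWHM_FACTOR * m.meta["true_sigma_major_mm"] == pytest.approx(2.3548, abs=1e-4)

    def test_circular_blob_rotation_invariant(self):
        a = generate_activation_map((41, 41), (2.0, 2.0), 0.7, 0.7, 0.0, 0.0, seed=0)
        b = generate_activation_map((41, 41), (2.0, 2.0), 0.7, 0.7, 1.1, 0.0, seed=0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            generate_activation_map((10, 10), (0.5, 0.5), 0.0, 0.5, 0.0, 0.0, seed=0)


class TestBlockDesign:
    def test_seven_blocks_cover_at_least_420s(self):
        paradigm = StimulusParadigm(30.0, 30.0, 7)
        response = SpatialMap(np.ones((1, 1)), 1.0)
        vs = generate_block_design_series(paradigm, response, volume_interval_s=3.0, seed=0)
        assert vs.duration_s >= 420.0

    def test_noiseless_percent_change_is_exact(self):
        paradigm = StimulusParadigm(30.0, 30.0, 2)
        response = SpatialMap(np.array([[1.0]]), 1.0)
        vs = generate_block_design_series(
            paradigm, response, volume_interval_s=3.0, baseline=50.0, amplitude=5.0, seed=0
        )
        on = vs.data[:, 0] > 50.0
        assert vs.data[on, 0] == pytest.approx(55.0)
        assert 100.0 * 5.0 / 50.0 == pytest.approx(10.0)

    def test_bit_identical_under_same_seed(self):
        paradigm = StimulusParadigm(30.0, 30.0, 2)
        response = SpatialMap(np.ones((2, 2)), 0.4)
        a = generate_block_design_series(paradigm, response, fs=500.0, seed=11)
        b = generate_block_design_series(paradigm, response, fs=500.0, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_both_sampling_arguments_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            generate_block_design_series(
                StimulusParadigm(30.0, 30.0, 1),
                SpatialMap(np.ones((1, 1)), 1.0),
                fs=500.0,
                volume_interval_s=3.0,
                seed=0,
            )
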