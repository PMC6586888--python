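import numpy as np
import pytest

from dynfc import (
    FWHM_FACTOR,
    SpatialMap,
    center_of_mass,
    extract_axis_profile,
    fit_elliptical_psf,
    fit_gaussian_1d,
    fit_gaussian_2d,
    major_axis_from_centers,
    upsample_map,
)
from dynfc.psf import AxisProfile
from dynfc.synth import generate_activation_map


def blob(sigma_major=1.0, sigma_minor=1.0, orientation=0.0, noise_sd=0.0, seed=0, n=81, res=0.1):
    c = (n - 1) / 2 * res
    return generate_activation_map(
        (n, n), (c, c), sigma_major, sigma_minor, orientation, noise_sd, seed, resolution_mm=res
    )


class TestUpsample:
    def test_constant_map_stays_constant(self):
        smap = SpatialMap(np.full((5, 5), 3.0), 0.4)
        up = upsample_map(smap, 0.1)
        np.testing.assert_allclose(up.values, 3.0)
        assert up.resolution_mm == 0.1

    def test_bilinear_exact_at_original_nodes(self, rng):
        smap = SpatialMap(rng.standard_normal((6, 6)), 0.4)
        up = upsample_map(smap, 0.1)
        np.testing.assert_allclose(up.values[::4, ::4], smap.values, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        rows = np.arange(6)[:, None] * np.ones((1, 6))
        smap = SpatialMap(rows, 0.4)
        up = upsample_map(smap, 0.2)
        expected = np.arange(0, 5.01, 0.5)[:, None] * np.ones((1, up.shape[1]))
        np.testing.assert_allclose(up.values, expected, atol=1e-12)

    def test_coarser_target_rejected(self):
        with pytest.raises(ValueError):
            upsample_map(SpatialMap(np.ones((4, 4)), 0.1), 0.4)


class TestCenterOfMass:
    def test_single_hot_pixel(self):
        values = np.zeros((5, 5))
        values[1, 3] = 1.0
        assert center_of_mass(SpatialMap(values, 0.5)) == (0.5, 1.5)

    def test_symmetric_blob_centered(self):
        smap = blob()
        com = center_of_mass(smap)
        assert com[0] == pytest.approx(4.0, abs=0.05)
        assert com[1] == pytest.approx(4.0, abs=0.05)

    def test_empty_suprathreshold_set_rejected(self):
        # the map is normalized internally, so only an unreachable threshold
        # can empty the supra-threshold set
        with pytest.raises(ValueError, match="threshold"):
            center_of_mass(SpatialMap(np.ones((4, 4)), 0.1), threshold=1.1)

    def test_two_equal_blobs_give_midpoint(self):
        values = np.zeros((3, 11))
        values[1, 2] = 1.0
        values[1, 8] = 1.0
        com = center_of_mass(SpatialMap(values, 1.0))
        assert com == (1.0, 5.0)


class TestAxisProfile:
    def test_floor_truncates_at_sigma_sqrt_2ln5(self):
        # exp(-x^2/2) = 0.2  =>  |x| = sqrt(2 ln 5) ~ 1.794
        smap = blob(sigma_major=1.0, sigma_minor=1.0, n=121)
        profile = extract_axis_profile(smap, (6.0, 6.0), 0.0, value_floor=0.2)
        half = np.sqrt(2 * np.log(5.0))
        assert profile.positions_mm.max() == pytest.approx(half, abs=0.11)
        assert profile.positions_mm.min() == pytest.approx(-half, abs=0.11)

    def test_flat_map_keeps_full_line(self):
        smap = SpatialMap(np.ones((5, 5)), 1.0)
        profile = extract_axis_profile(smap, (2.0, 2.0), 0.0, value_floor=0.2)
        assert profile.values.min() == 1.0
        assert profile.positions_mm.min() <= -2.0
        assert profile.positions_mm.max() >= 2.0

    def test_center_below_floor_rejected(self):
        values = np.zeros((5, 5))
        values[0, 0] = 1.0
        with pytest.raises(ValueError, match="floor"):
            extract_axis_profile(SpatialMap(values, 1.0), (4.0, 4.0), 0.0)


class TestGaussian1D:
    @pytest.mark.parametrize("sigma", [1.0, 0.5])
    def test_noiseless_fwhm_closed_form(self, sigma):
        x = np.arange(-4.0, 4.001, 0.1)
        fit = fit_gaussian_1d(AxisProfile(x, np.exp(-(x**2) / (2 * sigma**2))))
        assert fit.fwhm_mm == pytest.approx(FWHM_FACTOR * sigma, rel=1e-6)

    def test_amplitude_scaling_leaves_width_unchanged(self):
        x = np.arange(-3.0, 3.001, 0.1)
        y = np.exp(-(x**2) / 2)
        f1 = fit_gaussian_1d(AxisProfile(x, y))
        f10 = fit_gaussian_1d(AxisProfile(x, 10 * y))
        assert f10.fwhm_mm == pytest.approx(f1.fwhm_mm, rel=1e-9)
        assert f10.amplitude == pytest.approx(10 * f1.amplitude, rel=1e-6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_1d(AxisProfile(np.arange(4.0), np.ones(4)))


class TestEllipticalPsf:
    def test_axis_ratio_recovered_noiseless(self):
        smap = blob(sigma_major=1.0, sigma_minor=0.5)
        fit = fit_elliptical_psf(smap, 0.0)
        assert fit.fwhm_major_mm / fit.fwhm_minor_mm == pytest.approx(2.0, rel=0.01)
        assert fit.fwhm_major_mm == pytest.approx(FWHM_FACTOR, rel=1e-6)

    def test_circular_blob_area_formula(self):
        smap = blob(sigma_major=0.8, sigma_minor=0.8)
        fit = fit_elliptical_psf(smap, 0.0)
        assert fit.area_mm2 == pytest.approx(np.pi * (fit.fwhm_major_mm / 2) ** 2, rel=1e-9)

    def test_scale_invariance_of_fit(self):
        smap = blob(sigma_major=1.0, sigma_minor=0.6)
        scaled = SpatialMap(57.3 * smap.values, smap.resolution_mm)
        f1 = fit_elliptical_psf(smap, 0.0)
        f2 = fit_elliptical_psf(scaled, 0.0)
        assert f2.fwhm_major_mm == pytest.approx(f1.fwhm_major_mm, rel=1e-9)
        assert f2.area_mm2 == pytest.approx(f1.area_mm2, rel=1e-9)

    def test_fitted_fwhm_monotone_in_true_sigma(self):
        fwhms = [
            fit_elliptical_psf(blob(sigma_major=s, sigma_minor=s), 0.0).fwhm_major_mm
            for s in (0.4, 0.6, 0.8, 1.0, 1.2)
        ]
        assert np.all(np.diff(fwhms) > 0)

    def test_noisy_recovery_within_5_percent_over_20_seeds(self):
        fits = [
            fit_elliptical_psf(blob(1.0, 0.5, noise_sd=0.05, seed=s), 0.0) for s in range(20)
        ]
        maj = np.mean([f.fwhm_major_mm for f in fits])
        mino = np.mean([f.fwhm_minor_mm for f in fits])
        assert maj == pytest.approx(FWHM_FACTOR * 1.0, rel=0.05)
        assert mino == pytest.approx(FWHM_FACTOR * 0.5, rel=0.05)

    def test_2d_fit_agrees_with_sequential_profiles(self):
        smap = blob(sigma_major=1.0, sigma_minor=0.5)
        seq = fit_elliptical_psf(smap, 0.0)
        full = fit_gaussian_2d(smap)
        assert full.fwhm_major_mm == pytest.approx(seq.fwhm_major_mm, rel=0.01)
        assert full.fwhm_minor_mm == pytest.approx(seq.fwhm_minor_mm, rel=0.01)


class TestMajorAxis:
    def test_line_through_centers(self):
        centers = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        angle = major_axis_from_centers(centers)
        assert np.isclose(np.tan(angle), 1.0)

    def test_single_center_rejected(self):
        with pytest.raises(ValueError):
            major_axis_from_centers(np.array([[1.0, 2.0]]))
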