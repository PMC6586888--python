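"""Elliptical-Gaussian point-spread-function fitting for activation and
local-connectivity maps.

The procedure mirrors the classic activation-focus workflow: normalize the map
to its maximum, locate the centre of mass of the supra-0.7 region, extract 1-D
profiles along a supplied major axis (and its perpendicular minor axis) keeping
the contiguous stretch of values above 0.2, and fit each profile with a
Gaussian ``a * exp(-(x - mu)^2 / (2 sigma^2))``.  FWHM = 2*sqrt(2 ln 2)*sigma
and the reported area is the half-maximum ellipse
``pi * (FWHM_major / 2) * (FWHM_minor / 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import OptimizeWarning, curve_fit

from .containers import SpatialMap

__all__ = [
    "FWHM_FACTOR",
    "PsfFit",
    "Gaussian1DFit",
    "AxisProfile",
    "GaussianFitError",
    "upsample_map",
    "center_of_mass",
    "extract_axis_profile",
    "fit_gaussian_1d",
    "fit_elliptical_psf",
    "fit_gaussian_2d",
    "major_axis_from_centers",
]

#: FWHM = FWHM_FACTOR * sigma for a Gaussian.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

DEFAULT_COM_THRESHOLD = 0.7
DEFAULT_VALUE_FLOOR = 0.2


class GaussianFitError(RuntimeError):
    """Raised when a Gaussian fit fails to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class Gaussian1DFit:
    amplitude: float
    mean_mm: float
    sigma_mm: float
    fwhm_mm: float
    offset: float
    rss: float


@dataclass
class AxisProfile:
    positions_mm: np.ndarray  # signed distance from the centre along the axis
    values: np.ndarray


@dataclass
class PsfFit:
    center_mm: tuple[float, float]  # (row_mm, col_mm)
    fwhm_major_mm: float
    fwhm_minor_mm: float
    orientation_rad: float
    area_mm2: float
    goodness: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = np.pi * (self.fwhm_major_mm / 2.0) * (self.fwhm_minor_mm / 2.0)
        if not np.isclose(self.area_mm2, expected, rtol=1e-12, atol=1e-12):
            raise ValueError("area must equal pi * (FWHM_major/2) * (FWHM_minor/2)")
        if not self.fwhm_major_mm >= self.fwhm_minor_mm > 0:
            raise ValueError("need fwhm_major >= fwhm_minor > 0")


def _interpolator(smap: SpatialMap) -> RegularGridInterpolator:
    n_rows, n_cols = smap.shape
    rows = np.arange(n_rows) * smap.resolution_mm
    cols = np.arange(n_cols) * smap.resolution_mm
    return RegularGridInterpolator(
        (rows, cols), smap.values, method="linear", bounds_error=False, fill_value=np.nan
    )


def upsample_map(smap: SpatialMap, target_resolution_mm: float) -> SpatialMap:
    """Bilinear resampling onto a finer square grid covering the same extent."""
    if not target_resolution_mm > 0:
        raise ValueError(f"target_resolution_mm must be > 0, got {target_resolution_mm}")
    if target_resolution_mm >= smap.resolution_mm:
        raise ValueError(
            f"target resolution {target_resolution_mm} mm is not finer than the "
            f"source resolution {smap.resolution_mm} mm"
        )
    interp = _interpolator(smap)
    ext_r, ext_c = smap.extent_mm()
    rows = np.arange(0.0, ext_r + target_resolution_mm / 2, target_resolution_mm)
    cols = np.arange(0.0, ext_c + target_resolution_mm / 2, target_resolution_mm)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    values = interp(np.column_stack([rr.ravel(), cc.ravel()])).reshape(rr.shape)
    meta = dict(smap.meta)
    meta["upsampled_from_mm"] = smap.resolution_mm
    return SpatialMap(values, target_resolution_mm, meta)


def center_of_mass(
    smap: SpatialMap, threshold: float = DEFAULT_COM_THRESHOLD
) -> tuple[float, float]:
    """Intensity-weighted centroid (row_mm, col_mm) of pixels at or above
    ``threshold`` on the map normalized to unit maximum."""
    values = smap.normalized().values
    mask = values >= threshold
    if not mask.any():
        raise ValueError(f"no pixel reaches the centre-of-mass threshold {threshold}")
    rr, cc = np.nonzero(mask)
    weights = values[mask]
    row_mm = float(np.sum(rr * weights) / weights.sum()) * smap.resolution_mm
    col_mm = float(np.sum(cc * weights) / weights.sum()) * smap.resolution_mm
    return (row_mm, col_mm)


def _direction_vector(angle_rad: float) -> tuple[float, float]:
    # angle measured from the +col axis toward the +row axis
    return (np.sin(angle_rad), np.cos(angle_rad))


def extract_axis_profile(
    smap: SpatialMap,
    center_mm: tuple[float, float],
    axis_direction_rad: float,
    value_floor: float = DEFAULT_VALUE_FLOOR,
    *,
    sample_step_mm: float | None = None,
) -> AxisProfile:
    """Values along the line through ``center_mm`` in the given direction,
    truncated to the contiguous stretch >= ``value_floor`` containing the centre.

    The map is normalized to unit maximum before the floor is applied.
    """
    norm = smap.normalized()
    ext = norm.extent_mm()
    if not (0 <= center_mm[0] <= ext[0] and 0 <= center_mm[1] <= ext[1]):
        raise ValueError(f"center {center_mm} outside the map extent {ext}")
    step = sample_step_mm if sample_step_mm is not None else norm.resolution_mm
    dr, dc = _direction_vector(axis_direction_rad)
    half_span = float(np.hypot(*ext))
    n_steps = int(np.ceil(half_span / step))
    t = np.arange(-n_steps, n_steps + 1) * step  # includes t = 0 exactly
    rows = center_mm[0] + t * dr
    cols = center_mm[1] + t * dc
    interp = _interpolator(norm)
    vals = interp(np.column_stack([rows, cols]))
    inside = np.isfinite(vals)
    t, vals = t[inside], vals[inside]
    i_center = int(np.argmin(np.abs(t)))
    if vals[i_center] < value_floor:
        raise ValueError(
            f"centre value {vals[i_center]:.3g} is below the profile floor {value_floor}"
        )
    lo = i_center
    while lo > 0 and vals[lo - 1] >= value_floor:
        lo -= 1
    hi = i_center
    while hi < vals.size - 1 and vals[hi + 1] >= value_floor:
        hi += 1
    return AxisProfile(t[lo : hi + 1], vals[lo : hi + 1])


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _gauss_offset(x, a, mu, sigma, c):
    return _gauss(x, a, mu, sigma) + c


def fit_gaussian_1d(
    profile: AxisProfile, *, with_offset: bool = False
) -> Gaussian1DFit:
    """Least-squares Gaussian fit of a 1-D profile; FWHM = 2*sqrt(2 ln 2)*sigma."""
    x = np.asarray(profile.positions_mm, dtype=float)
    y = np.asarray(profile.values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 samples to fit a Gaussian, got {x.size}")
    a0 = float(y.max())
    mu0 = float(x[np.argmax(y)])
    spread = float(np.sqrt(np.sum(y * (x - mu0) ** 2) / np.sum(y)))
    sigma0 = max(spread, np.diff(np.sort(x)).min())
    try:
        with warnings.catch_warnings():
            # a perfect (noise-free) fit has a singular covariance; only the
            # point estimate is used here
            warnings.simplefilter("ignore", OptimizeWarning)
            if with_offset:
                popt, _ = curve_fit(
                    _gauss_offset, x, y, p0=[a0, mu0, sigma0, 0.0], maxfev=10000
                )
                a, mu, sigma, c = popt
            else:
                popt, _ = curve_fit(_gauss, x, y, p0=[a0, mu0, sigma0], maxfev=10000)
                a, mu, sigma = popt
                c = 0.0
    except RuntimeError as err:
        resid = y - _gauss(x, a0, mu0, sigma0)
        raise GaussianFitError(f"Gaussian fit did not converge: {err}", resid) from err
    sigma = abs(float(sigma))
    model = _gauss_offset(x, a, mu, sigma, c)
    rss = float(np.sum((y - model) ** 2))
    return Gaussian1DFit(float(a), float(mu), sigma, FWHM_FACTOR * sigma, float(c), rss)


def fit_elliptical_psf(
    smap: SpatialMap,
    major_axis_direction_rad: float,
    *,
    com_threshold: float = DEFAULT_COM_THRESHOLD,
    value_floor: float = DEFAULT_VALUE_FLOOR,
    sample_step_mm: float | None = 0.1,
    with_offset: bool = False,
) -> PsfFit:
    """Compose centre-of-mass, the two axis profiles and two 1-D Gaussian fits.

    The major-axis direction is supplied by the caller (derive it from multiple
    activation centres with :func:`major_axis_from_centers` when available); the
    minor axis is its perpendicular.  Profiles are resampled at
    ``sample_step_mm`` (default 0.10 mm) by bilinear interpolation.
    """
    norm = smap.normalized()
    center = center_of_mass(norm, com_threshold)
    fits = {}
    for label, angle in (
        ("major", major_axis_direction_rad),
        ("minor", major_axis_direction_rad + np.pi / 2),
    ):
        profile = extract_axis_profile(
            norm, center, angle, value_floor, sample_step_mm=sample_step_mm
        )
        fits[label] = fit_gaussian_1d(profile, with_offset=with_offset)
    fwhm_major = fits["major"].fwhm_mm
    fwhm_minor = fits["minor"].fwhm_mm
    orientation = major_axis_direction_rad
    swapped = False
    if fwhm_minor > fwhm_major:
        fwhm_major, fwhm_minor = fwhm_minor, fwhm_major
        orientation = major_axis_direction_rad + np.pi / 2
        swapped = True
    area = np.pi * (fwhm_major / 2.0) * (fwhm_minor / 2.0)
    goodness = fits["major"].rss + fits["minor"].rss
    return PsfFit(
        center,
        float(fwhm_major),
        float(fwhm_minor),
        float(orientation),
        float(area),
        float(goodness),
        {"major_fit": fits["major"], "minor_fit": fits["minor"], "axes_swapped": swapped},
    )


def _gauss2d(coords, a, mu_r, mu_c, sigma_major, sigma_minor, theta):
    r, c = coords
    u = (c - mu_c) * np.cos(theta) + (r - mu_r) * np.sin(theta)
    v = -(c - mu_c) * np.sin(theta) + (r - mu_r) * np.cos(theta)
    return a * np.exp(-(u**2 / (2 * sigma_major**2) + v**2 / (2 * sigma_minor**2)))


def fit_gaussian_2d(smap: SpatialMap, *, theta0: float = 0.0) -> PsfFit:
    """Full 2-D elliptical Gaussian fit, provided as a cross-check for the
    sequential two-profile procedure."""
    norm = smap.normalized()
    n_rows, n_cols = norm.shape
    rr, cc = np.meshgrid(
        np.arange(n_rows) * norm.resolution_mm,
        np.arange(n_cols) * norm.resolution_mm,
        indexing="ij",
    )
    finite = np.isfinite(norm.values)
    r, c, z = rr[finite], cc[finite], norm.values[finite]
    i_max = int(np.argmax(z))
    p0 = [1.0, r[i_max], c[i_max], norm.resolution_mm * 2, norm.resolution_mm * 2, theta0]
    try:
        popt, _ = curve_fit(_gauss2d, (r, c), z, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise GaussianFitError(f"2-D Gaussian fit did not converge: {err}") from err
    a, mu_r, mu_c, s_maj, s_min, theta = popt
    s_maj, s_min = abs(s_maj), abs(s_min)
    if s_min > s_maj:
        s_maj, s_min = s_min, s_maj
        theta += np.pi / 2
    fwhm_major, fwhm_minor = FWHM_FACTOR * s_maj, FWHM_FACTOR * s_min
    rss = float(np.sum((z - _gauss2d((r, c), *popt)) ** 2))
    return PsfFit(
        (float(mu_r), float(mu_c)),
        float(fwhm_major),
        float(fwhm_minor),
        float(theta % np.pi),
        float(np.pi * fwhm_major * fwhm_minor / 4.0),
        rss,
        {"amplitude": float(a)},
    )


def major_axis_from_centers(centers_mm: np.ndarray) -> float:
    """Direction (radians, from the +col axis toward +row) of the least-squares
    line through >= 2 activation centres, e.g. the individual digit foci."""
    pts = np.atleast_2d(np.asarray(centers_mm, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("need at least two activation centres to define an axis")
    centered = pts - pts.mean(axis=0)
    # principal direction of the (row, col) scatter
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d_row, d_col = vt[0]
    return float(np.arctan2(d_row, d_col))
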