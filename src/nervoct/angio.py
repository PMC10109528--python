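"""OCT angiography: decorrelation volumes, en-face maps, and vessel metrics.

Perfusion contrast comes from temporal decorrelation of the complex field
across the five repeated frames acquired at each slow-axis location:
static tissue keeps its speckle realization, flowing blood redraws it.
From registered en-face projections two study metrics are extracted:
vessel diameter (FWHM of a perpendicular intensity profile) and vessel
fraction (percent of a density ROI covered by the filtered vessel mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, median_filter, uniform_filter
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, opening

__all__ = [
    "EnFaceImage",
    "VesselMeasurement",
    "compute_angio",
    "project_enface",
    "remove_motion_lines",
    "register_enface",
    "measure_vessel_fwhm",
    "compute_vessel_fraction",
]


@dataclass
class EnFaceImage:
    """2D (y, x) projection over a depth window below the detected surface."""

    image: np.ndarray
    depth_window_um: tuple[float, float]
    timepoint: str = ""
    shift_applied: tuple[int, int] = (0, 0)


@dataclass
class VesselMeasurement:
    """One FWHM diameter measurement across a vessel."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    profile: np.ndarray
    fwhm_um: float
    timepoint: str = ""


def compute_angio(
    fields: np.ndarray, mode: str = "complex", kernel: int = 3
) -> np.ndarray:
    """Voxelwise decorrelation across repeated frames, in [0, 1].

    ``fields``: complex array (repeats, ..., channels).  For each adjacent
    repeat pair the magnitude of the normalized complex correlation is
    computed over a small spatial kernel (size ``kernel`` in every
    non-channel axis) plus the detection channels; decorrelation = 1 − its
    mean over pairs.  The kernel is essential: within one voxel the speckle
    field is a single complex amplitude whose change is invisible to a
    normalized single-sample correlation, whereas over a kernel of
    independent speckle cells the correlation estimates the inter-repeat
    amplitude correlation ρ (1 for static tissue, < 1 for flow).
    Identical repeats give 0 everywhere.  ``mode='intensity'`` is a
    normalized intensity-difference alternative.
    """
    f = np.asarray(fields)
    if f.shape[0] < 2:
        raise ValueError("angiography needs at least 2 repeats")
    size = (kernel,) * (f.ndim - 2)

    def _smooth(a: np.ndarray) -> np.ndarray:
        if kernel <= 1:
            return a
        if np.iscomplexobj(a):
            return uniform_filter(a.real, size, mode="nearest") + 1j * uniform_filter(
                a.imag, size, mode="nearest"
            )
        return uniform_filter(a, size, mode="nearest")

    pairs = []
    for r in range(f.shape[0] - 1):
        a, b = f[r], f[r + 1]
        if mode == "complex":
            corr = _smooth(np.sum(a * np.conj(b), axis=-1))
            ia = _smooth(np.sum(np.abs(a) ** 2, -1))
            ib = _smooth(np.sum(np.abs(b) ** 2, -1))
            num = np.abs(corr)
            den = np.sqrt(ia * ib)
        elif mode == "intensity":
            ia = _smooth(np.sum(np.abs(a) ** 2, -1))
            ib = _smooth(np.sum(np.abs(b) ** 2, -1))
            num = np.minimum(ia, ib)
            den = np.maximum(ia, ib)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
        pairs.append(1.0 - np.clip(g, 0.0, 1.0))
    return np.mean(pairs, axis=0)


def project_enface(
    volume: np.ndarray,
    surface: np.ndarray,
    depth_window_um: tuple[float, float],
    dz_um: float,
    timepoint: str = "",
) -> EnFaceImage:
    """Mean over a depth window below the per-A-line surface → (y, x) image."""
    lo_um, hi_um = depth_window_um
    lo = int(round(lo_um / dz_um))
    hi = int(round(hi_um / dz_um))
    if hi <= lo:
        raise ValueError("empty depth window")
    nz, nx, ny = volume.shape
    zz = np.arange(nz)[:, None, None]
    surf = np.where(surface >= 0, surface, 0)[None, :, :]
    inwin = (zz >= surf + lo) & (zz < surf + hi)
    v = np.where(np.isfinite(volume), volume, 0.0)
    with np.errstate(invalid="ignore"):
        img = (v * inwin).sum(axis=0) / np.maximum(inwin.sum(axis=0), 1)
    return EnFaceImage(image=img.T.copy(), depth_window_um=depth_window_um, timepoint=timepoint)


def remove_motion_lines(img: EnFaceImage, window: int = 15) -> EnFaceImage:
    """Suppress bright horizontal (whole-row) motion artifacts.

    Each row is divided by the ratio of its mean to a median-smoothed
    row-mean profile, flattening single-row outliers while leaving column
    (vessel) structure and the global mean essentially untouched.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    a = img.image
    m = a.mean(axis=1)
    m_smooth = median_filter(m, size=window, mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(m > 0, m_smooth / np.maximum(m, 1e-300), 1.0)
    out = a * gain[:, None]
    return EnFaceImage(
        image=out, depth_window_um=img.depth_window_um, timepoint=img.timepoint,
        shift_applied=img.shift_applied,
    )


def _standardize(a: np.ndarray) -> np.ndarray:
    a = a - a.mean()
    sd = a.std()
    return a / sd if sd > 0 else a


def register_enface(
    fixed: EnFaceImage,
    moving: EnFaceImage,
    max_shift: int | None = None,
    min_correlation: float = 0.2,
) -> tuple[tuple[int, int], EnFaceImage, EnFaceImage]:
    """Integer-pixel rigid registration by normalized cross-correlation.

    Returns the (dy, dx) shift that maps ``moving`` onto ``fixed`` and the
    two images cropped to their overlap.  Raises ``RuntimeError`` when the
    best normalized correlation falls below ``min_correlation``.
    Rotation/stretch are deliberately not corrected; the crop-to-overlap
    strategy absorbs them.
    """
    f = fixed.image.astype(float)
    m = moving.image.astype(float)
    h, w = m.shape
    ones_f = np.ones_like(f)
    ones_m = np.ones_like(m)

    def _corr(a, b):
        return fftconvolve(a, b[::-1, ::-1], mode="full")

    # masked NCC: per-shift overlap statistics via FFT running sums
    n_ov = np.maximum(_corr(ones_f, ones_m), 1.0)
    s_fm = _corr(f, m)
    s_f, s_f2 = _corr(f, ones_m), _corr(f**2, ones_m)
    s_m, s_m2 = _corr(ones_f, m), _corr(ones_f, m**2)
    cov = s_fm - s_f * s_m / n_ov
    var_f = np.maximum(s_f2 - s_f**2 / n_ov, 0.0)
    var_m = np.maximum(s_m2 - s_m**2 / n_ov, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = cov / np.maximum(np.sqrt(var_f * var_m), 1e-12)

    dy_grid = np.arange(ncc.shape[0]) - (h - 1)
    dx_grid = np.arange(ncc.shape[1]) - (w - 1)
    quarter = 0.25 * min(f.size, m.size)
    ncc[n_ov < quarter] = -np.inf
    if max_shift is not None:
        ncc[np.abs(dy_grid) > max_shift, :] = -np.inf
        ncc[:, np.abs(dx_grid) > max_shift] = -np.inf
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    peak = float(ncc[iy, ix])
    if not np.isfinite(peak) or peak < min_correlation:
        raise RuntimeError(f"registration failed: peak NCC {peak:.3f} < {min_correlation}")
    dy, dx = int(dy_grid[iy]), int(dx_grid[ix])

    fy0, fy1 = max(0, dy), min(fixed.image.shape[0], h + dy)
    fx0, fx1 = max(0, dx), min(fixed.image.shape[1], w + dx)
    f_crop = fixed.image[fy0:fy1, fx0:fx1]
    m_crop = moving.image[fy0 - dy : fy1 - dy, fx0 - dx : fx1 - dx]
    out_f = EnFaceImage(f_crop, fixed.depth_window_um, fixed.timepoint, (0, 0))
    out_m = EnFaceImage(m_crop, moving.depth_window_um, moving.timepoint, (dy, dx))
    return (dy, dx), out_f, out_m


def measure_vessel_fwhm(
    img: EnFaceImage,
    segment: tuple[tuple[float, float], tuple[float, float]],
    pitch_um_px: float,
    min_prominence: float = 0.0,
    n_samples: int | None = None,
    timepoint: str = "",
) -> VesselMeasurement:
    """FWHM diameter (µm) along a profile sampled across a vessel.

    Background is the mean of the outer 20% of samples at both ends;
    the width is linearly interpolated at background + (peak−background)/2.
    Raises ``ValueError`` when no interior maximum clears the background by
    ``min_prominence``.
    """
    (y0, x0), (y1, x1) = segment
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = n_samples or max(int(np.ceil(length)) * 2 + 1, 9)
    t = np.linspace(0.0, 1.0, n)
    coords = np.stack([y0 + t * (y1 - y0), x0 + t * (x1 - x0)])
    prof = map_coordinates(img.image.astype(float), coords, order=1, mode="nearest")
    n_bg = max(1, int(0.2 * n / 2))
    background = float(np.concatenate([prof[:n_bg], prof[-n_bg:]]).mean())
    full_pk = int(np.argmax(prof))
    if full_pk < n_bg or full_pk > n - 1 - n_bg:
        raise ValueError("profile maximum lies in the background region")
    pk = full_pk
    peak = float(prof[pk])
    if peak <= background + min_prominence:
        raise ValueError("no interior maximum above background + prominence")
    half = background + 0.5 * (peak - background)

    def _cross(seq: np.ndarray) -> float:
        prev = pk
        for i in seq:
            if prof[i] < half:
                # interpolate between the sample below half and the one above
                frac = (half - prof[i]) / (prof[prev] - prof[i])
                return i + frac * (prev - i)
            prev = i
        return float(seq[-1]) if len(seq) else float(pk)

    left = _cross(np.arange(pk - 1, -1, -1))
    right = _cross(np.arange(pk + 1, n))
    width_samples = right - left
    step_px = length / (n - 1)
    fwhm_um = width_samples * step_px * pitch_um_px
    return VesselMeasurement(segment, prof, float(fwhm_um), timepoint)


def compute_vessel_fraction(
    img: EnFaceImage,
    roi_mask: np.ndarray | None = None,
    threshold: float | str = "otsu",
    opening_radius: int = 1,
    closing_radius: int = 1,
    rescale_percentiles: tuple[float, float] | None = (1.0, 99.0),
) -> tuple[float, np.ndarray]:
    """Percent of the density ROI covered by the filtered vessel mask.

    Pipeline: percentile contrast rescale → global threshold (Otsu by
    default, or a fixed value in rescaled units) → binary opening then
    closing.  Returns (percent, binary vessel mask).
    """
    a = img.image.astype(float)
    roi = np.ones_like(a, dtype=bool) if roi_mask is None else roi_mask.astype(bool)
    if not roi.any():
        raise ValueError("empty density ROI")
    if rescale_percentiles is not None:
        lo, hi = np.percentile(a[roi], rescale_percentiles)
        a = np.clip((a - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    if threshold == "otsu":
        vals = a[roi]
        thr = threshold_otsu(vals) if vals.max() > vals.min() else vals.max()
    else:
        thr = float(threshold)
    mask = a > thr
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    percent = 100.0 * np.count_nonzero(mask & roi) / np.count_nonzero(roi)
    return percent, mask
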