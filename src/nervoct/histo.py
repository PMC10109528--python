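"""Immunofluorescence pixel quantification.

RGB channels map to myelin (red, anti-P0), axons (green, anti-β-tubulin-III)
and cell nuclei (blue, DAPI).  Quantification deliberately uses
presence/absence masks rather than brightness, so slide-to-slide staining
and exposure variation does not enter the metric: each channel is masked,
positive pixels are counted inside manually drawn fascicle ROIs, and the
myelin/axon count ratio is derived.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath

try:  # optional: Otsu rule for real (noisy) slides
    from skimage.filters import threshold_otsu
except ImportError:  # pragma: no cover
    threshold_otsu = None

__all__ = ["mask_channel", "count_pixels", "myelin_axon_ratio", "polygon_mask"]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def mask_channel(
    img: np.ndarray, channel: str, rule: str = "positive", offset: float = 0.0
) -> np.ndarray:
    """Binary presence/absence mask of one fluorescence channel.

    rule='positive' (default): pixel > offset after background-offset
    subtraction; offset 0 suits noise-free acquisitions.  rule='otsu'
    thresholds with Otsu's method for slides with residual background.
    """
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    plane = np.asarray(img[..., _CHANNELS[channel]], dtype=float)
    if rule == "positive":
        return plane > offset
    if rule == "otsu":
        if threshold_otsu is None:  # pragma: no cover
            raise RuntimeError("scikit-image required for the otsu rule")
        if plane.max() == plane.min():
            return plane > plane.max()  # constant plane: nothing to separate
        return plane > threshold_otsu(plane)
    raise ValueError(f"unknown masking rule {rule!r}")


def polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside a polygon.

    ``polygon`` is (N, 2) in (row, col) vertex order; pixel (i, j) has its
    center at coordinates (i, j).
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    inside = MplPath(poly).contains_points(pts)
    return inside.reshape(shape)


def count_pixels(mask: np.ndarray, polygon: np.ndarray) -> int:
    """Number of mask-positive pixels whose centers lie inside the ROI polygon."""
    roi = polygon_mask(mask.shape, polygon)
    return int(np.count_nonzero(mask & roi))


def myelin_axon_ratio(red_count: int, green_count: int) -> float | None:
    """Myelin/axon pixel-count ratio; ``None`` when the axon count is zero."""
    if green_count == 0:
        return None
    return red_count / green_count
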