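"""Synthetic immunofluorescence images and footprint records.

These generators provide ground-truthed inputs for the histology and gait
analyses: an RGB image with known per-channel positive-pixel counts inside
each fascicle ROI (red = myelin, green = axons, blue = nuclei), and a
footprint-parameter record whose injury severity is a single dial d∈[0,1]
(d = 0 reproduces an uninjured gait exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..gait import GaitRecord

__all__ = ["IHCComposition", "IHCImage", "simulate_ihc_image", "simulate_gait"]

_CHANNEL_IDX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class IHCComposition:
    """Target positive-pixel fractions per fascicle and channel.

    ``fractions`` maps fascicle label -> {'red': f, 'green': f, 'blue': f}.
    """

    image_shape: tuple[int, int] = (360, 520)
    roi_half: int = 55  # half-side of each square fascicle ROI
    centers: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"L": (180, 110), "C": (180, 260), "R": (180, 410)}
    )
    fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            lab: {"red": 0.45, "green": 0.35, "blue": 0.12} for lab in ("L", "C", "R")
        }
    )
    intensity: int = 180  # positive-pixel brightness (value is irrelevant to counts)


@dataclass
class IHCImage:
    """RGB image + fascicle ROI polygons + exact ground-truth counts."""

    rgb: np.ndarray  # uint8 (H, W, 3)
    rois: dict[str, np.ndarray]  # label -> (N, 2) polygon in (row, col)
    true_counts: dict[str, dict[str, int]]  # label -> channel -> count


def simulate_ihc_image(spec: IHCComposition | None = None, seed: int = 0) -> IHCImage:
    """Draw random positive pixels per channel inside each fascicle ROI.

    The realized fraction is binomial around the target (within ~1%
    absolute for the default ROI size); the exact realized counts are
    stored as ground truth.  Pixels outside the tissue ROIs stay zero
    (noise-free background).
    """
    spec = spec or IHCComposition()
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rois: dict[str, np.ndarray] = {}
    counts: dict[str, dict[str, int]] = {}
    r = spec.roi_half
    for lab, (cy, cx) in spec.centers.items():
        if not (r <= cy < h - r and r <= cx < w - r):
            raise ValueError(f"ROI {lab} does not fit in the image")
        # polygon strictly containing the pixel block [cy-r+1, cy+r-1] x ...
        rois[lab] = np.array(
            [
                (cy - r + 0.5, cx - r + 0.5),
                (cy - r + 0.5, cx + r - 0.5),
                (cy + r - 0.5, cx + r - 0.5),
                (cy + r - 0.5, cx - r + 0.5),
            ]
        )
        block = (slice(cy - r + 1, cy + r), slice(cx - r + 1, cx + r))
        n_px = (2 * r - 1) ** 2
        counts[lab] = {}
        for ch, frac in spec.fractions[lab].items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
            mask = rng.random((2 * r - 1, 2 * r - 1)) < frac
            plane = rgb[..., _CHANNEL_IDX[ch]]
            plane[block][mask] = spec.intensity
            counts[lab][ch] = int(mask.sum())
        assert all(abs(c / n_px - spec.fractions[lab][ch]) < 0.05 for ch, c in counts[lab].items())
    return IHCImage(rgb=rgb, rois=rois, true_counts=counts)


def simulate_gait(
    deficit: float,
    seed: int = 0,
    animal: str = "",
    timepoint: str = "",
    normal_means: tuple[float, float, float] = (28.0, 18.0, 9.0),
    noise_sd: float = 0.0,
) -> GaitRecord:
    """Footprint record at injury severity ``deficit`` ∈ [0, 1].

    The injured pattern lengthens the print (dragging foot) and narrows the
    toe spreads; at deficit 1 the shifts are +35% PL, −45% TS, −40% IT —
    roughly an SFI of −80.  deficit 0 returns experimental = normal.
    """
    if not 0.0 <= deficit <= 1.0:
        raise ValueError("deficit must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pl, ts, it = (m * (1 + noise_sd * rng.standard_normal()) for m in normal_means)
    return GaitRecord(
        e_print_length=pl * (1 + 0.35 * deficit),
        e_toe_spread=ts * (1 - 0.45 * deficit),
        e_intermediary=it * (1 - 0.40 * deficit),
        n_print_length=pl,
        n_toe_spread=ts,
        n_intermediary=it,
        animal=animal,
        timepoint=timepoint,
    )
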