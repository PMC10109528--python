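"""Fascicle-level metric extraction and group statistics.

The study statistic is the per-animal D7−D1 change of a fascicle-ROI mean,
averaged within stimulation groups:

    Δmetric = avg over stim group of (D7 2D-fascicle mean − D1 2D-fascicle mean)

Per timepoint, five analysis regions spanning the stimulation span are
summarized (25-frame averages, arithmetic or coherent for the axis), a
fascicle-ROI mean is taken per region, regions are averaged per animal,
and the D7−baseline difference feeds a two-way (group × fascicle) ANOVA
with Tukey-adjusted pairwise group contrasts per fascicle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .histo import polygon_mask
from .recon import circular_mean_axis

__all__ = [
    "FascicleROI",
    "MetricRecord",
    "average_frames",
    "pick_analysis_regions",
    "extract_fascicle_mean",
    "delta_metric",
    "group_stats",
    "repeated_measures_stats",
]

AXIS_CHANNELS = {"axis"}


@dataclass(frozen=True)
class FascicleROI:
    """Simple polygon (px, in the averaged-frame (z, x) plane) for one fascicle."""

    polygon: np.ndarray  # (N, 2) vertices, (row=z, col=x)
    label: str  # L / C / R
    timepoint: str = ""
    animal: str = ""

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon_mask(shape, self.polygon)


@dataclass(frozen=True)
class MetricRecord:
    animal: str
    group: str  # SC / SL1 / SL2
    fascicle: str  # L / C / R
    channel: str  # retardation / attenuation / dopu / axis / ...
    timepoint: str  # B / S1 / S2 / R1 / R2 / D7
    value: float
    region: int = 0
    valid: bool = True


def average_frames(
    volume: np.ndarray, center: int, n: int = 25, mode: str = "arithmetic"
) -> np.ndarray:
    """Average ``n`` cross-sectional frames (slow axis) around ``center``.

    ``mode='coherent'`` treats pixels as axis angles (deg, mod 180) and
    averages on the doubled-angle circle; pixels whose resultant length is
    below 0.3 (incoherent orientations) come back NaN.
    """
    if n % 2 == 0:
        raise ValueError("frame count must be odd")
    half = n // 2
    if center - half < 0 or center + half >= volume.shape[2]:
        raise ValueError("averaging window outside the volume")
    win = volume[:, :, center - half : center + half + 1]
    if mode == "arithmetic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(win, axis=2)
    if mode == "coherent":
        z = np.exp(2j * np.deg2rad(win))
        z = np.where(np.isfinite(win), z, 0.0)
        cnt = np.isfinite(win).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = z.sum(axis=2) / np.maximum(cnt, 1)
        mean = np.degrees(0.5 * np.angle(res)) % 180.0
        mean[(np.abs(res) < 0.3) | (cnt == 0)] = np.nan
        return mean
    raise ValueError(f"unknown averaging mode {mode!r}")


def pick_analysis_regions(
    extent: int, span: tuple[int, int], k: int = 5, n_frames: int = 25
) -> list[int]:
    """k evenly spaced window centers across the stimulation span.

    Centers sit at the midpoints of k equal sub-spans; windows are clipped
    to the volume extent and a warning is issued if they must overlap.
    """
    lo, hi = span
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 <= lo < hi <= extent):
        raise ValueError("span outside the volume extent")
    centers = [int(round(lo + (i + 0.5) * (hi - lo) / k)) for i in range(k)]
    half = n_frames // 2
    centers = [min(max(c, half), extent - half - 1) for c in centers]
    if k > 1 and (hi - lo) < k * n_frames:
        warnings.warn("analysis windows overlap within the span", stacklevel=2)
    return centers


def extract_fascicle_mean(
    frame: np.ndarray,
    roi: FascicleROI,
    channel: str,
    animal: str = "",
    group: str = "",
    timepoint: str | None = None,
    region: int = 0,
    validity: np.ndarray | None = None,
    min_valid_px: int = 50,
) -> MetricRecord:
    """Mean channel value over valid in-ROI pixels (circular mean for axis)."""
    mask = roi.mask(frame.shape)
    if validity is not None:
        mask &= validity
    vals = frame[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_valid_px:
        return MetricRecord(
            animal, group, roi.label, channel, timepoint or roi.timepoint,
            float("nan"), region, valid=False,
        )
    mean = circular_mean_axis(vals) if channel in AXIS_CHANNELS else float(vals.mean())
    return MetricRecord(
        animal, group, roi.label, channel, timepoint or roi.timepoint, mean, region,
    )


def records_to_frame(records: "list[MetricRecord] | pd.DataFrame") -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def delta_metric(
    records: "list[MetricRecord] | pd.DataFrame",
    baseline: str = "B",
    followup: str = "D7",
    reference_group: str = "SC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal D7−baseline differences and the group-level Δ table.

    The five-region values are first averaged per (animal, fascicle,
    channel, timepoint); animals missing either timepoint are excluded
    from that cell.  Returns (per-animal deltas, group table).  The group
    table carries mean, SD, n and a derived percent-vs-reference column
    100·(Δ_group − Δ_ref)/|Δ_ref| — one defensible normalization of a
    "percent change vs sham" figure, labeled as such.
    """
    df = records_to_frame(records)
    df = df[df["valid"]] if "valid" in df else df
    key = ["animal", "group", "fascicle", "channel"]
    per_tp = (
        df[df["timepoint"].isin([baseline, followup])]
        .groupby(key + ["timepoint"], as_index=False)["value"]
        .mean()
    )
    wide = per_tp.pivot_table(index=key, columns="timepoint", values="value")
    wide = wide.dropna(subset=[c for c in (baseline, followup) if c in wide.columns])
    if baseline not in wide.columns or followup not in wide.columns:
        raise ValueError("records lack matching baseline/followup timepoints")
    deltas = wide.reset_index()
    deltas["delta"] = deltas[followup] - deltas[baseline]

    grp = (
        deltas.groupby(["group", "fascicle", "channel"])["delta"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    ref = grp[grp["group"] == reference_group].set_index(["fascicle", "channel"])["mean"]

    def _pct(row) -> float:
        r = ref.get((row["fascicle"], row["channel"]), np.nan)
        if not np.isfinite(r) or r == 0:
            return float("nan")
        return 100.0 * (row["mean"] - r) / abs(r)

    grp["pct_vs_ref"] = grp.apply(_pct, axis=1)
    return deltas, grp


def group_stats(
    deltas: pd.DataFrame,
    value_col: str = "delta",
    alpha: float = 0.05,
) -> dict:
    """Two-way (group × fascicle) ANOVA + Tukey group contrasts per fascicle.

    ``deltas`` must hold one row per (animal, group, fascicle) with the
    per-animal Δ value.  Returns {'anova': table, 'tukey': DataFrame} with
    Tukey-adjusted p-values for every pairwise group contrast within each
    fascicle.  Raises on singular designs (a group×fascicle cell with no
    data, or fewer than 2 animals in a group).
    """
    d = deltas.dropna(subset=[value_col])
    counts = d.groupby(["group", "fascicle"])[value_col].count()
    if (counts < 2).any() or counts.size < d["group"].nunique() * d["fascicle"].nunique():
        raise ValueError("singular design: need >=2 animals per group×fascicle cell")
    model = smf.ols(f"{value_col} ~ C(group) * C(fascicle)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    rows = []
    for fasc, sub in d.groupby("fascicle"):
        if sub["group"].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub[value_col], sub["group"], alpha=alpha)
        tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        tbl.insert(0, "fascicle", fasc)
        rows.append(tbl)
    tukey = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return {"anova": anova, "tukey": tukey}


def repeated_measures_stats(
    values: pd.DataFrame,
    depvar: str = "value",
    subject: str = "animal",
    within: str = "timepoint",
    alpha: float = 0.05,
) -> dict:
    """Repeated-measures ANOVA across timepoints + Tukey post hoc.

    Used for the time-course vessel metrics (B, S1, S2, R1, R2, D7).
    """
    rm = AnovaRM(values, depvar=depvar, subject=subject, within=[within]).fit()
    res = pairwise_tukeyhsd(values[depvar], values[within], alpha=alpha)
    tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return {"anova": rm.anova_table, "tukey": tukey}
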