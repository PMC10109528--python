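"""Parameter-recovery evaluation of reconstructed channels against phantom truth.

Glue used by the validation suite and the reproduction script: given a
:class:`~nervoct.synthdata.phantom.PhantomTruth` and the reconstructed
:class:`~nervoct.recon.ChannelSet` of the same scene, quantify how well
each fascicle's birefringence (cumulative retardation), optic-axis
orientation and attenuation coefficient are recovered, and how the
calibration stripes read after optic-axis calibration.

Margins erode the fascicle interiors before averaging: the axial PSF
mixes adjacent voxels, so the few pixels nearest a tissue boundary are
partial-volume mixtures of both sides and are excluded from the
truth comparison (they carry no single ground-truth value).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recon import ChannelSet, calibrate_optic_axis, circular_mean_axis
from .synthdata.phantom import PhantomTruth

__all__ = ["stripe_calibration_masks", "calibrate_channels", "evaluate_recovery"]


def stripe_calibration_masks(
    truth: PhantomTruth,
    channels: ChannelSet,
    ret_range_deg: tuple[float, float] = (15.0, 140.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel masks of the 0°/45° stripes where the axis is well defined.

    Uses the shallow stripe portion where cumulative round-trip retardation
    sits between the axis floor and the 180° eigen-order ambiguity.
    """
    lo, hi = ret_range_deg
    good = (
        np.isfinite(channels.axis_deg)
        & np.isfinite(channels.retardation_deg)
        & (channels.retardation_deg > lo)
        & (channels.retardation_deg < hi)
        & channels.validity
    )
    p0 = truth.stripe_mask("P0") & good
    p45 = truth.stripe_mask("P45") & good
    if not p0.any() or not p45.any():
        raise ValueError("no axis-valid voxels inside a calibration stripe")
    return p0, p45


def calibrate_channels(truth: PhantomTruth, channels: ChannelSet) -> ChannelSet:
    """Apply stripe-based optic-axis calibration in place; returns ``channels``."""
    p0, p45 = stripe_calibration_masks(truth, channels)
    cal, offset, _ = calibrate_optic_axis(channels.axis_deg, p0, p45)
    channels.axis_deg = cal
    channels.axis_calibration_offset_deg = offset
    return channels


def _eroded_column_bounds(
    mask2d: np.ndarray, margin_z: int, margin_x: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column top/bottom of a convex 2D (z, x) mask, eroded by margins."""
    nz, nx = mask2d.shape
    col_any = mask2d.any(axis=0)
    ztop = np.argmax(mask2d, axis=0) + margin_z
    zbot = nz - 1 - np.argmax(mask2d[::-1], axis=0) - margin_z
    xs = np.nonzero(col_any)[0]
    if margin_x > 0 and xs.size:
        col_any = col_any.copy()
        col_any[: xs.min() + margin_x] = False
        col_any[max(xs.max() - margin_x + 1, 0) :] = False
    ok = col_any & (zbot > ztop)
    return ok, ztop, zbot


def evaluate_recovery(
    truth: PhantomTruth,
    channels: ChannelSet,
    margin_z: int = 4,
    margin_x: int = 2,
) -> pd.DataFrame:
    """Per-fascicle recovery table plus stripe readings.

    Returns one row per fascicle with:

    * ``ret_ratio`` — recovered cumulative round-trip retardation across the
      eroded fascicle interior (bottom minus top, per column, averaged)
      divided by the ground truth 2·δ·thickness;
    * ``axis_deg`` / ``axis_err_deg`` — circular mean of the calibrated axis
      over valid interior voxels vs the true orientation;
    * ``mu_ratio`` — mean recovered attenuation over valid interior voxels
      divided by the true µ;

    and two stripe rows with the calibrated axis reading of P0 and P45.
    """
    geo = truth.geometry
    dz = geo.pitch_axial_um
    ret = channels.retardation_deg
    rows = []
    for name, f in geo.fascicles.items():
        mask = truth.fascicle_mask(name)
        mask2d = mask[:, :, 0] if mask.shape[2] else mask.any(axis=2)
        ok, ztop, zbot = _eroded_column_bounds(mask2d, margin_z, margin_x)
        ix = np.nonzero(ok)[0]
        # retardation: per-column difference across the eroded interior
        rec = ret[zbot[ix][:, None], ix[:, None], np.arange(ret.shape[2])[None, :]] - ret[
            ztop[ix][:, None], ix[:, None], np.arange(ret.shape[2])[None, :]
        ]
        tru = np.broadcast_to(
            2.0 * f.delta_deg_um * dz * (zbot - ztop)[ix][:, None], rec.shape
        )
        good = np.isfinite(rec) & (tru > 20.0)
        ret_ratio = float(np.mean(rec[good] / tru[good])) if good.any() else float("nan")

        interior = np.zeros_like(mask)
        zz = np.arange(mask.shape[0])[:, None]
        int2d = np.zeros_like(mask2d)
        int2d[:, ix] = (zz >= ztop[ix][None, :]) & (zz <= zbot[ix][None, :])
        interior = np.broadcast_to(int2d[:, :, None], mask.shape) & mask

        ax_sel = interior & np.isfinite(channels.axis_deg) & channels.validity
        axis = circular_mean_axis(channels.axis_deg[ax_sel])
        axis_err = (axis - f.theta_deg + 90.0) % 180.0 - 90.0

        mu_sel = interior & np.isfinite(channels.attenuation_mm) & channels.validity
        mu_ratio = float(np.nanmean(channels.attenuation_mm[mu_sel]) / (f.mu_per_um * 1e3))

        rows.append(
            {
                "region": name,
                "kind": "fascicle",
                "ret_ratio": ret_ratio,
                "axis_deg": axis,
                "axis_err_deg": float(axis_err),
                "mu_ratio": mu_ratio,
            }
        )

    p0, p45 = stripe_calibration_masks(truth, channels)
    for sname, smask, target in (("P0", p0, 0.0), ("P45", p45, 45.0)):
        reading = circular_mean_axis(channels.axis_deg[smask])
        err = (reading - target + 90.0) % 180.0 - 90.0
        rows.append(
            {
                "region": sname,
                "kind": "stripe",
                "ret_ratio": float("nan"),
                "axis_deg": reading,
                "axis_err_deg": float(err),
                "mu_ratio": float("nan"),
            }
        )
    return pd.DataFrame(rows)
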