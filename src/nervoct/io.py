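"""File I/O: HDF5 volumes, float32 multi-page TIFF channels, tidy CSV tables.

Every file carries a ``schema_version`` key; readers raise
:class:`SchemaError` on a mismatch instead of mis-parsing silently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .metrics import records_to_frame
from .recon import ChannelSet
from .synthdata.phantom import NerveGeometry, PhantomTruth
from .synthdata.tomogram import AcquisitionConfig, RawAcquisition

SCHEMA_VERSION = "1"

__all__ = [
    "SchemaError",
    "write_raw_h5",
    "read_raw_h5",
    "write_truth_h5",
    "read_truth_h5",
    "write_channels",
    "read_channels",
    "write_records_csv",
    "read_records_csv",
]


class SchemaError(RuntimeError):
    """File schema missing or incompatible with this package version."""


def _check_version(found: str | None, where: str) -> None:
    if found is None:
        raise SchemaError(f"{where}: missing schema_version")
    if str(found) != SCHEMA_VERSION:
        raise SchemaError(f"{where}: schema_version {found!r} != {SCHEMA_VERSION!r}")


# ---------------------------------------------------------------------------
# HDF5: raw acquisitions and phantom truths
# ---------------------------------------------------------------------------

def write_raw_h5(path: str | Path, raw: RawAcquisition) -> None:
    cfg = raw.config
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "raw_acquisition"
        d = f.create_dataset("field", data=raw.field, compression="gzip", compression_opts=1)
        d.attrs["pitch_axial_um"] = raw.pitch_axial_um
        d.attrs["pitch_lateral_um"] = raw.pitch_lateral_um
        g = f.create_group("config")
        for k in (
            "center_wavelength_nm", "bandwidth_nm", "repeats", "snr_db",
            "axis_offset_deg", "axis_flip", "seed", "apply_psf",
        ):
            v = getattr(cfg, k)
            if v is not None:
                g.attrs[k] = v
        g.create_dataset("system_unitary", data=np.asarray(cfg.system_unitary))
        g.create_dataset("input_states", data=np.asarray(cfg.input_states))


def read_raw_h5(path: str | Path) -> RawAcquisition:
    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("schema_version"), str(path))
        d = f["field"]
        g = f["config"]
        cfg = AcquisitionConfig(
            center_wavelength_nm=float(g.attrs["center_wavelength_nm"]),
            bandwidth_nm=float(g.attrs["bandwidth_nm"]),
            repeats=int(g.attrs["repeats"]),
            snr_db=float(g.attrs["snr_db"]) if "snr_db" in g.attrs else None,
            system_unitary=g["system_unitary"][()],
            axis_offset_deg=float(g.attrs["axis_offset_deg"]),
            axis_flip=bool(g.attrs["axis_flip"]),
            input_states=g["input_states"][()],
            seed=int(g.attrs["seed"]),
            apply_psf=bool(g.attrs["apply_psf"]),
        )
        return RawAcquisition(
            field=d[()],
            config=cfg,
            pitch_axial_um=float(d.attrs["pitch_axial_um"]),
            pitch_lateral_um=float(d.attrs["pitch_lateral_um"]),
        )


_TRUTH_MAPS = (
    "backscatter", "mu", "delta", "theta", "depol", "rho",
    "fascicle_labels", "stripe_labels",
)


def write_truth_h5(path: str | Path, truth: PhantomTruth) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "phantom_truth"
        for name in _TRUTH_MAPS:
            f.create_dataset(name, data=getattr(truth, name), compression="gzip", compression_opts=1)
        f.attrs["geometry_json"] = json.dumps(
            dataclasses.asdict(truth.geometry), default=lambda o: list(o)
        )


def read_truth_h5(path: str | Path) -> PhantomTruth:
    from .synthdata.phantom import FascicleSpec, StripeSpec, VesselSpec

    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("schema_version"), str(path))
        maps = {name: f[name][()] for name in _TRUTH_MAPS}
        gd = json.loads(f.attrs["geometry_json"])
    gd["shape"] = tuple(gd["shape"])
    gd["fascicles"] = {k: FascicleSpec(**v) for k, v in gd["fascicles"].items()}
    gd["stripes"] = {
        k: StripeSpec(**{**v, "x_range": tuple(v["x_range"])}) for k, v in gd["stripes"].items()
    }
    gd["vessels"] = tuple(VesselSpec(**v) for v in gd["vessels"])
    return PhantomTruth(geometry=NerveGeometry(**gd), **maps)


# ---------------------------------------------------------------------------
# ChannelSet: one float32 TIFF per channel + a JSON sidecar
# ---------------------------------------------------------------------------

_CHANNEL_ARRAYS = (
    "reflectance_db", "attenuation_mm", "retardation_deg", "axis_deg",
    "dopu", "bwoa_rgb", "validity", "surface",
)


def write_channels(outdir: str | Path, channels: ChannelSet) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _CHANNEL_ARRAYS:
        a = getattr(channels, name)
        tifffile.imwrite(
            out / f"{name}.tif", np.asarray(a, dtype=np.float32), photometric="minisblack"
        )
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "channel_set",
        "pitch_axial_um": channels.pitch_axial_um,
        "pitch_lateral_um": channels.pitch_lateral_um,
        "noise_floor_db": channels.noise_floor_db,
        "axis_calibration_offset_deg": channels.axis_calibration_offset_deg,
    }
    (out / "channels.json").write_text(json.dumps(sidecar, indent=2))


def read_channels(indir: str | Path) -> ChannelSet:
    ind = Path(indir)
    try:
        sidecar = json.loads((ind / "channels.json").read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise SchemaError(f"{ind}: unreadable channels.json sidecar: {e}") from e
    _check_version(sidecar.get("schema_version"), str(ind))
    arrays = {}
    for name in _CHANNEL_ARRAYS:
        a = tifffile.imread(ind / f"{name}.tif")
        if name == "validity":
            a = a.astype(bool)
        elif name == "surface":
            a = a.astype(np.int64)
        arrays[name] = a
    return ChannelSet(
        **arrays,
        pitch_axial_um=sidecar["pitch_axial_um"],
        pitch_lateral_um=sidecar["pitch_lateral_um"],
        noise_floor_db=sidecar["noise_floor_db"],
        axis_calibration_offset_deg=sidecar["axis_calibration_offset_deg"],
    )


# ---------------------------------------------------------------------------
# tidy CSV tables
# ---------------------------------------------------------------------------

def write_records_csv(path: str | Path, records: "list[MetricRecord] | pd.DataFrame") -> None:
    df = records_to_frame(records).copy()
    df.insert(0, "schema_version", SCHEMA_VERSION)
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "schema_version" not in df.columns:
        raise SchemaError(f"{path}: missing schema_version column")
    _check_version(str(df["schema_version"].iloc[0]), str(path))
    return df.drop(columns="schema_version")
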