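"""Functional indices from walking-track footprints and Von Frey withdrawal forces.

SFI/TFI are footprint-geometry composites: ≈ −8.8 in an uninjured animal
and ≈ −100 with complete sciatic/tibial loss.  They combine the
experimental-vs-normal relative differences of print length (PL), toe
spread (TS, digits 1–5) and intermediary toe spread (IT, digits 2–4).

Coefficients follow the classical walking-track literature and are kept as
module-level constants so alternative published sets can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GaitRecord", "sfi", "tfi", "von_frey_summary", "SFI_COEFFS", "TFI_COEFFS"]

# (PL term, TS term, IT term, intercept)
SFI_COEFFS = (-38.3, 109.5, 13.3, -8.8)
TFI_COEFFS = (-37.2, 104.4, 45.6, -8.8)


@dataclass(frozen=True)
class GaitRecord:
    """Footprint parameters (mm) for one animal at one timepoint.

    e_* are from the experimental (operated) side, n_* from the normal side.
    """

    e_print_length: float
    e_toe_spread: float
    e_intermediary: float
    n_print_length: float
    n_toe_spread: float
    n_intermediary: float
    animal: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        vals = (
            self.e_print_length,
            self.e_toe_spread,
            self.e_intermediary,
            self.n_print_length,
            self.n_toe_spread,
            self.n_intermediary,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all footprint lengths must be > 0")


def _index(rec: GaitRecord, coeffs: tuple[float, float, float, float]) -> float:
    c_pl, c_ts, c_it, c0 = coeffs
    pl = (rec.e_print_length - rec.n_print_length) / rec.n_print_length
    ts = (rec.e_toe_spread - rec.n_toe_spread) / rec.n_toe_spread
    it = (rec.e_intermediary - rec.n_intermediary) / rec.n_intermediary
    return c_pl * pl + c_ts * ts + c_it * it + c0


def sfi(rec: GaitRecord) -> float:
    """Sciatic function index; −8.8 when experimental equals normal."""
    return _index(rec, SFI_COEFFS)


def tfi(rec: GaitRecord) -> float:
    """Tibial function index; −8.8 when experimental equals normal."""
    return _index(rec, TFI_COEFFS)


def von_frey_summary(
    ipsilateral: "list[float] | np.ndarray", contralateral: "list[float] | np.ndarray"
) -> pd.Series:
    """Mean ± SD withdrawal force per hind limb and the ipsi/contra ratio.

    Each input is the series of recorded withdrawal forces (typically 5
    trials per limb).  SD is the sample standard deviation (ddof=1), 0.0
    for a single trial.
    """
    ipsi = np.asarray(ipsilateral, dtype=float)
    contra = np.asarray(contralateral, dtype=float)
    if ipsi.size == 0 or contra.size == 0:
        raise ValueError("each limb needs at least one valid trial")

    def _sd(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1)) if a.size > 1 else 0.0

    return pd.Series(
        {
            "ipsi_mean": float(ipsi.mean()),
            "ipsi_sd": _sd(ipsi),
            "contra_mean": float(contra.mean()),
            "contra_sd": _sd(contra),
            "ratio": float(ipsi.mean() / contra.mean()),
        }
    )
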