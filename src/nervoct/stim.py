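"""Shannon-model stimulation dosing and waveform synthesis.

The Shannon model is an empirical safety boundary for neural electrical
stimulation relating charge per phase Q (µC) and charge density per phase
D (µC/cm²):  log10(D) = k − log10(Q), i.e. k = log10(Q·D).  Larger k means
a more damaging dose; k ≳ 1.85 is associated with tissue damage.

Frequency does not enter k; it is carried on the spec only for waveform
synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StimSpec", "ShannonDose", "shannon_k", "generate_waveform", "GROUP_SPECS"]


@dataclass(frozen=True)
class StimSpec:
    """Stimulation amplitude/timing and electrode geometry for one study arm.

    Charge density is computed over the lateral area of the positive
    (0.2 mm deinsulated) cylindrical lead.
    """

    amplitude_ma: float  # current amplitude I (mA)
    frequency_hz: float  # pulse repetition rate f (Hz)
    pulse_width_us: float = 100.0  # per-phase pulse width PW (µs)
    interphase_delay_us: float = 400.0  # gap between cathodic and anodic phase (µs)
    electrode_diameter_mm: float = 0.05  # lead wire diameter d (mm)
    deinsulated_length_mm: float = 0.2  # positive-lead deinsulated length L (mm)
    group: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_ma < 0 or self.frequency_hz < 0:
            raise ValueError("amplitude and frequency must be >= 0")
        if self.pulse_width_us <= 0:
            raise ValueError("pulse width must be > 0")
        if self.electrode_diameter_mm <= 0 or self.deinsulated_length_mm <= 0:
            raise ValueError("electrode geometry must be > 0")


#: The three study arms: sham control and two suprathreshold stimulation levels.
GROUP_SPECS: dict[str, StimSpec] = {
    "SC": StimSpec(0.0, 0.0, group="SC"),
    "SL1": StimSpec(3.4, 50.0, group="SL1"),
    "SL2": StimSpec(6.8, 100.0, group="SL2"),
}


@dataclass(frozen=True)
class ShannonDose:
    charge_uC: float  # Q, charge per phase (µC)
    area_cm2: float  # A, electrode lateral area (cm²)
    charge_density_uC_cm2: float  # D = Q/A (µC/cm²)
    k: float  # Shannon k = log10(Q·D)


def shannon_k(spec: StimSpec) -> ShannonDose | None:
    """Compute the Shannon dose for a stimulation spec.

    Q = I·PW (mA·µs = nC → µC), A = π·d·L (full lateral cylinder area of
    the positive lead), D = Q/A, k = log10(Q·D).

    Returns ``None`` for a sham (zero-amplitude) spec, where k is undefined.
    """
    if spec.amplitude_ma == 0:
        return None
    charge_uC = spec.amplitude_ma * 1e-3 * spec.pulse_width_us  # mA·µs → µC
    area_cm2 = math.pi * (spec.electrode_diameter_mm / 10.0) * (
        spec.deinsulated_length_mm / 10.0
    )  # mm → cm
    density = charge_uC / area_cm2
    k = math.log10(charge_uC * density)
    return ShannonDose(charge_uC, area_cm2, density, k)


def generate_waveform(
    spec: StimSpec, duration_s: float, sample_rate_hz: float
) -> np.ndarray:
    """Synthesize the cathodic-first charge-balanced biphasic square wave.

    Each period (1/f): −I for PW, 0 for the interphase delay, +I for PW,
    then 0 until the next period.  Net charge per period is exactly zero.
    A sham spec (I=0 or f=0) yields an all-zero trace.

    Returns the sampled current trace in mA.
    """
    n = int(round(duration_s * sample_rate_hz))
    trace = np.zeros(n, dtype=np.float64)
    if spec.amplitude_ma == 0 or spec.frequency_hz == 0:
        return trace
    dt_us = 1e6 / sample_rate_hz
    if dt_us > spec.pulse_width_us / 10:
        raise ValueError("sample rate must resolve the pulse width (>=10 samples/phase)")
    period_us = 1e6 / spec.frequency_hz
    active_us = 2 * spec.pulse_width_us + spec.interphase_delay_us
    if active_us > period_us:
        raise ValueError("pulse phases overlap: f·(2·PW + delay) exceeds one period")
    pw_n = int(round(spec.pulse_width_us / dt_us))
    gap_n = int(round(spec.interphase_delay_us / dt_us))
    period_n = int(round(period_us / dt_us))
    for start in range(0, n, period_n):
        cath = slice(start, min(start + pw_n, n))
        anod = slice(start + pw_n + gap_n, min(start + 2 * pw_n + gap_n, n))
        trace[cath] = -spec.amplitude_ma
        trace[anod] = +spec.amplitude_ma
        # trim a trailing partial period so every emitted period balances
        if start + period_n > n and (cath.stop - cath.start) != (anod.stop - anod.start):
            trace[start:] = 0.0
    return trace
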