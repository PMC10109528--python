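"""Shared fixtures: one reconstructed phantom acquisition reused across tests.

The simulate→reconstruct chain is the expensive part of the suite, so the
standard study-condition acquisition (30 dB SNR, axial PSF, random
detection unitary, unknown axis offset) is built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from nervoct.recon import reconstruct
from nervoct.recovery import calibrate_channels
from nervoct.synthdata import (
    AcquisitionConfig,
    build_nerve_truth,
    random_unitary,
    simulate_tomogram,
    small_geometry,
)


@pytest.fixture(scope="session")
def phantom_truth():
    return build_nerve_truth(small_geometry(ny=24), seed=1)


@pytest.fixture(scope="session")
def study_acquisition(phantom_truth):
    """30 dB, PSF on, arbitrary detection fiber and instrument frame."""
    cfg = AcquisitionConfig(
        repeats=1,
        snr_db=30.0,
        seed=1,
        apply_psf=True,
        system_unitary=random_unitary(7),
        axis_offset_deg=23.0,
    )
    return simulate_tomogram(phantom_truth, cfg)


@pytest.fixture(scope="session")
def study_channels(phantom_truth, study_acquisition):
    ch = reconstruct(study_acquisition)
    return calibrate_channels(phantom_truth, ch)


@pytest.fixture(scope="session")
def clean_acquisition(phantom_truth):
    """Noise-free, PSF-free acquisition with an identity system."""
    cfg = AcquisitionConfig(repeats=1, snr_db=None, seed=1, apply_psf=False)
    return simulate_tomogram(phantom_truth, cfg)


@pytest.fixture(scope="session")
def clean_channels(phantom_truth, clean_acquisition):
    ch = reconstruct(clean_acquisition)
    return calibrate_channels(phantom_truth, ch)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
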