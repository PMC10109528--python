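"""Forward simulation of polarization-diverse swept-source OCT tomograms.

The simulator starts at complex-valued tomograms (post-FFT): per tissue
column a one-way cumulative Jones matrix is accumulated as an ordered
product of thin-slab linear retarders; the round-trip matrix follows from
reciprocity (transpose sandwich), and the measured field is

    E(z) = U_sys · J_rt(z) · e_in · √backscatter · exp(−∫µ dz) · s(z)

with s(z) unit circular complex Gaussian speckle, plus additive complex
Gaussian detector noise set by the surface SNR.  Input polarization
alternates between two linearly independent states on adjacent A-lines
(even A-line: state A, odd: state B — both sample the same tissue column).
Static voxels reuse one speckle realization across the repeated frames;
voxels inside vessels redraw speckle between repeats with first-order
correlation ρ, which is what OCT angiography decorrelation estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .phantom import PhantomTruth

__all__ = [
    "AcquisitionConfig",
    "RawAcquisition",
    "axial_psf_fwhm",
    "simulate_tomogram",
    "rotation_unitary",
    "random_unitary",
    "H45_INPUT_STATES",
]

#: Default input-state pair (columns): horizontal and vertical linear.
#: Any non-degenerate pair reconstructs the Jones matrix; an orthonormal
#: pair keeps the detector-noise covariance isotropic after the basis
#: inversion, so the optic-axis estimate carries no orientation-dependent
#: noise bias.  A non-orthogonal alternative (H and +45°) is provided for
#: experiments with state-pair conditioning.
DEFAULT_INPUT_STATES = np.eye(2, dtype=np.complex128)

H45_INPUT_STATES = np.array(
    [[1.0, 1.0 / math.sqrt(2)], [0.0, 1.0 / math.sqrt(2)]], dtype=np.complex128
)


def axial_psf_fwhm(center_wavelength_nm: float, bandwidth_nm: float) -> float:
    """Round-trip axial coherence length (FWHM, µm) of a Gaussian source in air.

    FWHM = (2 ln 2 / π) · λ0² / Δλ.  For the study source (1310 nm, 110 nm
    bandwidth) this evaluates to 6.88 µm.
    """
    if center_wavelength_nm <= 0 or bandwidth_nm <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    return (2 * math.log(2) / math.pi) * center_wavelength_nm**2 / bandwidth_nm / 1000.0


def rotation_unitary(angle_deg: float) -> np.ndarray:
    """Real rotation by ``angle_deg`` (a special case of an SU(2) unitary)."""
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]], dtype=np.complex128)


def random_unitary(seed: int) -> np.ndarray:
    """A random SU(2) matrix (unit determinant) — a generic detection fiber."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
    q, r = np.linalg.qr(z)
    q = q * (np.diagonal(r) / np.abs(np.diagonal(r)))
    return q / np.sqrt(np.linalg.det(q))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition and system parameters for the forward model.

    ``snr_db`` is the ratio of mean surface signal power to total noise
    power; ``None`` disables noise.  The instrument's polarization state is
    split into a detection-side unitary (``system_unitary``) and an
    instrument-frame axis offset/chirality (``axis_offset_deg`` /
    ``axis_flip``): the former cancels in surface-relative retardation and
    DOPU, the latter is what the 0°/45° stripe calibration recovers.
    """

    center_wavelength_nm: float = 1310.0
    bandwidth_nm: float = 110.0
    repeats: int = 5
    snr_db: float | None = 30.0
    system_unitary: np.ndarray = field(default_factory=lambda: np.eye(2, dtype=np.complex128))
    axis_offset_deg: float = 0.0
    axis_flip: bool = False
    input_states: np.ndarray = field(default_factory=lambda: DEFAULT_INPUT_STATES.copy())
    seed: int = 0
    apply_psf: bool = True

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.snr_db is not None and self.snr_db <= 0:
            raise ValueError("snr_db must be positive (or None for noise-free)")
        u = np.asarray(self.system_unitary)
        if u.shape != (2, 2) or not np.allclose(u.conj().T @ u, np.eye(2), atol=1e-8):
            raise ValueError("system_unitary must be a 2x2 unitary matrix")
        s = np.asarray(self.input_states)
        if abs(np.linalg.det(s)) < 1e-6:
            raise ValueError("input states are degenerate (collinear)")


@dataclass
class RawAcquisition:
    """Complex tomogram stack, shape (repeat, y, A-line x, z, channel HV).

    Adjacent even/odd A-lines sample the same tissue column with input
    states A and B respectively, so the x extent is twice the phantom's.
    """

    field: np.ndarray
    config: AcquisitionConfig
    pitch_axial_um: float
    pitch_lateral_um: float

    @property
    def n_repeats(self) -> int:
        return self.field.shape[0]


def _retarder_slab(phi_rad: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Linear-retarder Jones matrices, shape (..., 2, 2)."""
    a = np.exp(0.5j * phi_rad)
    b = np.conj(a)
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    out = np.empty(phi_rad.shape + (2, 2), dtype=np.complex128)
    out[..., 0, 0] = a * c * c + b * s * s
    out[..., 0, 1] = (a - b) * c * s
    out[..., 1, 0] = out[..., 0, 1]
    out[..., 1, 1] = a * s * s + b * c * c
    return out


def round_trip_matrices(truth: PhantomTruth, cfg: AcquisitionConfig) -> np.ndarray:
    """Per-voxel measured polarization transfer matrix U·J_rt, (nz,nx,ny,2,2).

    The one-way matrix is the ordered product of thin-slab retarders from
    the surface down; reciprocity gives J_rt = J_owᵀ · J_ow, which is
    symmetric up to the detection unitary.
    """
    nz, nx, ny = truth.shape
    dz = truth.geometry.pitch_axial_um
    theta_eff = truth.theta * (-1.0 if cfg.axis_flip else 1.0) + cfg.axis_offset_deg
    phi = np.deg2rad(truth.delta * dz)
    th = np.deg2rad(theta_eff)
    u = np.asarray(cfg.system_unitary, dtype=np.complex128)

    out = np.empty((nz, nx, ny, 2, 2), dtype=np.complex64)
    j_ow = np.broadcast_to(np.eye(2, dtype=np.complex128), (nx, ny, 2, 2)).copy()
    for iz in range(nz):
        slab = _retarder_slab(phi[iz], th[iz])
        j_ow = slab @ j_ow
        j_rt = np.swapaxes(j_ow, -1, -2) @ j_ow
        out[iz] = (u @ j_rt).astype(np.complex64)
    return out


def simulate_tomogram(truth: PhantomTruth, cfg: AcquisitionConfig) -> RawAcquisition:
    """Forward-simulate a polarization-diverse OCT acquisition of a phantom."""
    nz, nx, ny = truth.shape
    geo = truth.geometry
    dz = geo.pitch_axial_um
    rng = np.random.default_rng(cfg.seed)

    m = round_trip_matrices(truth, cfg)  # (nz,nx,ny,2,2)

    # amplitude envelope: √backscatter · exp(−∫µ dz)  ⇒ |E|² ∝ b·exp(−2∫µ dz)
    optical_depth = np.cumsum(truth.mu, axis=0) * dz
    env = np.sqrt(truth.backscatter) * np.exp(-optical_depth)

    # per-voxel responses to the two input states (before speckle/noise)
    states = np.asarray(cfg.input_states, dtype=np.complex64)
    resp_a = np.einsum("zxyij,j->zxyi", m, states[:, 0]).astype(np.complex64)
    resp_b = np.einsum("zxyij,j->zxyi", m, states[:, 1]).astype(np.complex64)
    del m

    def _cgauss(shape) -> np.ndarray:
        return (rng.normal(size=shape) + 1j * rng.normal(size=shape)) / math.sqrt(2)

    # static speckle and static depolarized component, shared across repeats
    s_static = _cgauss((nz, nx, ny)).astype(np.complex64)
    p = truth.depol
    has_depol = bool(np.any(p > 0))
    if has_depol:
        # unit total power over the 2-vector, matching the polarized part
        g_static = (_cgauss((nz, nx, ny, 2)) / math.sqrt(2)).astype(np.complex64)

    psf_kernel = None
    if cfg.apply_psf:
        fwhm_px = axial_psf_fwhm(cfg.center_wavelength_nm, cfg.bandwidth_nm) / dz
        sigma = fwhm_px / (2 * math.sqrt(2 * math.log(2)))
        half = max(1, int(math.ceil(3 * sigma)))
        zz = np.arange(-half, half + 1)
        psf_kernel = np.exp(-(zz**2) / (2 * sigma**2))
        psf_kernel /= psf_kernel.sum()

    # noise scale from the mean surface signal power (both channels, state A)
    sigma_noise = 0.0
    if cfg.snr_db is not None:
        surf = np.argmax(truth.backscatter > 0, axis=0)  # (nx, ny)
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        p_surf = (env[surf, ix, iy][..., None] * np.abs(resp_a[surf, ix, iy])) ** 2
        p_mean = float(p_surf.sum(axis=-1)[truth.backscatter[surf, ix, iy] > 0].mean())
        noise_power = p_mean * 10 ** (-cfg.snr_db / 10)
        sigma_noise = math.sqrt(noise_power / 4)  # per channel, per quadrature

    vessel = truth.rho < 1.0
    raw = np.empty((cfg.repeats, ny, 2 * nx, nz, 2), dtype=np.complex64)
    s_prev = s_static
    for r in range(cfg.repeats):
        if r == 0:
            s_r = s_static
        else:
            s_r = s_prev.copy()
            if np.any(vessel):
                innov = _cgauss((int(vessel.sum()),)).astype(np.complex64)
                rho_v = truth.rho[vessel]
                s_r[vessel] = rho_v * s_prev[vessel] + np.sqrt(1 - rho_v**2) * innov
        s_prev = s_r

        for k, resp in enumerate((resp_a, resp_b)):
            e = resp * (env * s_r)[..., None]
            if has_depol:
                amp = np.sqrt(np.sum(np.abs(resp) ** 2, axis=-1, keepdims=True))
                e = np.sqrt(1 - p)[..., None] * e + (
                    np.sqrt(p)[..., None] * env[..., None] * amp * g_static
                )
            if psf_kernel is not None:
                e = convolve1d(e.real, psf_kernel, axis=0, mode="nearest") + 1j * convolve1d(
                    e.imag, psf_kernel, axis=0, mode="nearest"
                )
            if sigma_noise > 0:
                e = e + sigma_noise * (
                    rng.normal(size=e.shape) + 1j * rng.normal(size=e.shape)
                )
            # (z, x, y, ch) → (y, x, z, ch), interleave on even/odd A-lines
            raw[r, :, k::2, :, :] = np.transpose(e, (2, 1, 0, 3)).astype(np.complex64)

    return RawAcquisition(
        field=raw,
        config=cfg,
        pitch_axial_um=geo.pitch_axial_um,
        pitch_lateral_um=geo.pitch_lateral_um,
    )
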