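"""Jones-matrix reconstruction of the six PSOCT data channels.

From a polarization-diverse acquisition this module recovers, per voxel:

* reflectance (dB) — total backscattered power,
* attenuation µ̂ (1/mm) — depth-resolved estimator from the intensity tail,
* cumulative round-trip phase retardation (deg) relative to the tissue
  surface — insensitive to the detection unitary by construction,
* optic-axis orientation (deg mod 180), calibrated against the two
  stabilizer stripes at 0° and 45°,
* DOPU — spatial uniformity of the normalized Stokes state,
* BwOA — an HSV composite (hue = axis, saturation = local retardance,
  value = reflectance) rendered as RGB.

A validity mask marks the depth range where polarization-sensitive
quantities are trustworthy (DOPU and reflectance above thresholds): in
scattering nerve only part of the structurally visible depth is
polarization-valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import uniform_filter, uniform_filter1d

from .synthdata.tomogram import RawAcquisition

__all__ = [
    "JonesVolume",
    "ChannelSet",
    "ReconParams",
    "assemble_jones",
    "compute_reflectance",
    "detect_surface",
    "compute_attenuation",
    "compute_retardation",
    "compute_optic_axis",
    "calibrate_optic_axis",
    "compute_dopu",
    "local_retardance",
    "compute_bwoa",
    "reconstruct",
    "circular_mean_axis",
]


@dataclass
class JonesVolume:
    """Per-voxel measured 2×2 polarization transfer matrix, (nz, nx, ny, 2, 2)."""

    j: np.ndarray
    pitch_axial_um: float
    pitch_lateral_um: float
    repeat: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.j.shape[:3]


@dataclass
class ReconParams:
    """Tunable reconstruction thresholds (all configurable)."""

    noise_floor_db: float | None = None  # None → estimated from above-surface voxels
    surface_margin_db: float = 10.0  # surface: refl > floor + margin, 3 px run
    surface_run: int = 3
    valid_margin_db: float = 5.0  # validity: refl > floor + margin
    dopu_min: float = 0.6  # validity: DOPU >= dopu_min
    dopu_kernel: tuple[int, int, int] = (3, 9, 1)  # (z, x, y) voxels
    atten_tail_mask: int = 20  # last M pixels masked invalid
    atten_tail_correction: bool = True
    axis_floor_deg: float = 10.0  # axis undefined below this retardation
    jones_smooth_xy: int = 3  # lateral averaging of relative Jones matrices
    bwoa_sat_cap_deg_um: float = 0.4  # local one-way retardance display cap
    bwoa_value_range_db: tuple[float, float] = (0.0, 40.0)  # above noise floor


@dataclass
class ChannelSet:
    """The six reconstructed channels on one (nz, nx, ny) grid."""

    reflectance_db: np.ndarray
    attenuation_mm: np.ndarray  # 1/mm, NaN where invalid
    retardation_deg: np.ndarray  # cumulative round-trip, NaN above surface
    axis_deg: np.ndarray  # calibrated if stripe ROIs were given; NaN = masked
    dopu: np.ndarray
    bwoa_rgb: np.ndarray  # (nz, nx, ny, 3) float in [0, 1]
    validity: np.ndarray  # bool, polarization-valid voxels
    surface: np.ndarray  # (nx, ny) surface depth index, -1 if none
    pitch_axial_um: float = 1.0
    pitch_lateral_um: float = 1.0
    noise_floor_db: float = 0.0
    axis_calibration_offset_deg: float | None = None


# ---------------------------------------------------------------------------
# Jones assembly and scalar channels
# ---------------------------------------------------------------------------

def assemble_jones(raw: RawAcquisition, repeat: int = 0) -> JonesVolume:
    """Pair even/odd A-lines into per-voxel measured Jones matrices.

    J_meas = [response(A) | response(B)] · [e_A | e_B]⁻¹; the result is the
    transfer matrix in the canonical H/V basis, independent of which
    (non-degenerate) input pair was used.
    """
    states = np.asarray(raw.config.input_states, dtype=np.complex128)
    if abs(np.linalg.det(states)) < 1e-6:
        raise ValueError("degenerate input states")
    s_inv = np.linalg.inv(states).astype(np.complex64)
    f = raw.field[repeat]  # (y, x_raw, z, ch)
    e_a = np.transpose(f[:, 0::2], (2, 1, 0, 3))  # (z, x, y, ch)
    e_b = np.transpose(f[:, 1::2], (2, 1, 0, 3))
    j_resp = np.stack([e_a, e_b], axis=-1)  # columns = responses
    j = j_resp @ s_inv
    return JonesVolume(
        j=j.astype(np.complex64),
        pitch_axial_um=raw.pitch_axial_um,
        pitch_lateral_um=raw.pitch_lateral_um,
        repeat=repeat,
    )


def compute_reflectance(j: JonesVolume, floor_db: float | None = None) -> np.ndarray:
    """Total backscattered power in dB, floored so empty voxels stay finite."""
    p = np.sum(np.abs(j.j) ** 2, axis=(-2, -1))
    if floor_db is None:
        floor_db = 10 * np.log10(max(p.max(), 1e-30)) - 80.0
    lin_floor = 10 ** (floor_db / 10)
    return 10 * np.log10(np.maximum(p, lin_floor))


def estimate_noise_floor(refl_db: np.ndarray, n_top: int = 8) -> float:
    """Noise floor (dB) from the shallowest voxels, which lie above tissue."""
    return float(np.median(refl_db[:n_top]))


def detect_surface(
    refl_db: np.ndarray, noise_floor_db: float, margin_db: float = 10.0, run: int = 3
) -> np.ndarray:
    """First depth where reflectance exceeds floor+margin for ``run`` px.

    Returns (nx, ny) int indices; −1 where no surface is found.
    """
    above = refl_db > noise_floor_db + margin_db
    if run > 1:
        above = (
            uniform_filter1d(above.astype(np.float32), size=run, axis=0, origin=-(run // 2))
            > 1 - 0.5 / run
        )
    hit = above.any(axis=0)
    idx = np.argmax(above, axis=0)
    return np.where(hit, idx, -1)


def compute_attenuation(
    intensity: np.ndarray,
    dz_um: float,
    tail_mask: int = 20,
    noise_level: float | None = None,
    tail_correction: bool = True,
) -> np.ndarray:
    """Depth-resolved attenuation estimator, µ̂ in 1/mm.

    µ̂_i = ln(1 + I_i / Σ_{j>i} I_j) / (2Δz): exact for a discretely sampled
    exponential decay with a fully decayed tail.  ``noise_level`` (linear
    intensity) is subtracted first.  ``tail_correction`` handles the
    incomplete-decay boundary bias of thin samples: the last depth with
    signal is located per A-line, the local per-pixel decay ratio q is
    estimated just above it, and the missing tail I_end·q/(1−q) is added —
    this completes the exponential where light exits the tissue bottom
    un-backscattered, which otherwise inflates µ̂ throughout the sample.
    Voxels within ``tail_mask`` pixels of the signal end (or below it, or
    with a zero tail) are returned as NaN.
    """
    i = np.asarray(intensity, dtype=np.float64)
    if np.any(i < 0):
        raise ValueError("intensity must be non-negative")
    if noise_level is not None:
        i = np.maximum(i - noise_level, 0.0)
    nz = i.shape[0]
    cols = i.shape[1:]
    # tail sum  T_i = Σ_{j>i} I_j
    tail = np.flip(np.cumsum(np.flip(i, axis=0), axis=0), axis=0) - i
    tail_measured = tail.copy()
    zz = np.arange(nz).reshape((nz,) + (1,) * len(cols))
    if tail_correction:
        # last depth with signal (3× the residual noise, or any signal at all
        # when the input is noise-subtracted exactly)
        thresh = 3.0 * noise_level if noise_level else 0.0
        has_sig = i > max(thresh, 1e-300)
        z_end = np.where(has_sig.any(axis=0), nz - 1 - np.argmax(has_sig[::-1], axis=0), -1)
        # fit the local decay rate over the last K pixels of signal in the
        # log domain on laterally pooled intensity: the pooled log profile is
        # nearly noise-free, so the convex q/(1−q) continuation term
        #   Σ_{j>end} I_j = I(end)·q/(1−q)
        # is evaluated at a stable q instead of a speckled one (a noisy q
        # passed through 1/(1−q) would bias µ̂ downward)
        k_fit = max(8, min(24, nz // 4))
        # the last few samples are contaminated by the axial-PSF boundary
        # (and by partial-volume smearing at a physical tissue bottom), so
        # the decay fit ends a guard above z_end and extrapolates through it
        edge_guard = 4
        z_fit = np.maximum(z_end - edge_guard, 1)
        i_pool = i
        if cols and max(cols) >= 3:
            i_pool = uniform_filter(i, size=(1,) + (7,) * len(cols), mode="nearest")
        log_i = np.log(np.maximum(i_pool, 1e-300))
        in_win = (zz > z_fit - k_fit) & (zz <= z_fit) & (z_end >= 0)
        n_w = np.maximum(in_win.sum(axis=0), 2)
        sx = (zz * in_win).sum(axis=0)
        sy = (log_i * in_win).sum(axis=0)
        sxx = (zz**2 * in_win).sum(axis=0)
        sxy = (zz * log_i * in_win).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (n_w * sxy - sx * sy) / np.maximum(n_w * sxx - sx**2, 1e-300)
            log_end = sy / n_w + slope * (z_end - sx / n_w)
        q = np.clip(np.exp(slope), 1e-6, 0.995)
        # magnitude from the fit, rescaled to this column's own level
        col_lvl = (i * in_win).sum(axis=0) / n_w
        pool_lvl = (i_pool * in_win).sum(axis=0) / n_w
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(pool_lvl > 0, col_lvl / np.maximum(pool_lvl, 1e-300), 1.0)
        i_end_fit = np.exp(log_end) * scale
        t_extra = np.where(z_end >= 0, i_end_fit * q / (1 - q), 0.0)
        tail = tail + t_extra[None, ...]
        end = np.where(z_end >= 0, z_end, 0)
    else:
        end = np.full(cols, nz - 1) if cols else nz - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_px = 0.5 * np.log1p(i / tail)  # per-pixel, round-trip corrected
    mu = mu_px / dz_um * 1000.0  # 1/mm
    mu[~np.isfinite(mu)] = np.nan
    mu[tail_measured <= 0] = np.nan  # zero measured tail → invalid, not an error
    mu[zz > np.asarray(end) - tail_mask] = np.nan
    return mu


# ---------------------------------------------------------------------------
# polarization channels
# ---------------------------------------------------------------------------

def _gather_surface(j: np.ndarray, surface: np.ndarray) -> np.ndarray:
    nx, ny = surface.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    zs = np.clip(surface, 0, j.shape[0] - 1)
    return j[zs, ix, iy]


def _relative_matrices(
    j: JonesVolume, surface: np.ndarray, smooth_xy: int = 1
) -> np.ndarray:
    """N(z) = J(z_surf)⁻¹·J(z): the detection unitary cancels exactly.

    With ``smooth_xy`` > 1 the relative matrices are normalized to unit
    determinant (sign-aligned on the real part of the trace, which is
    positive for a retarder below 180°) and averaged over a lateral
    (x, y) kernel: same-retarder matrices add coherently while additive
    noise averages down, which suppresses the rectified upward bias of the
    eigenvalue-split estimate at low retardance.
    """
    js = _gather_surface(j.j.astype(np.complex128), surface)  # (nx, ny, 2, 2)
    det = np.linalg.det(js)
    bad = np.abs(det) < 1e-20
    js_inv = np.linalg.inv(np.where(bad[..., None, None], np.eye(2), js))
    n = np.einsum("xyij,zxyjk->zxyik", js_inv, j.j.astype(np.complex128))
    n[:, bad] = np.nan
    if smooth_xy > 1:
        detn = n[..., 0, 0] * n[..., 1, 1] - n[..., 0, 1] * n[..., 1, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            root = np.sqrt(detn)
            nu = n / root[..., None, None]
        sgn = np.where(np.real(nu[..., 0, 0] + nu[..., 1, 1]) < 0, -1.0, 1.0)
        nu = nu * sgn[..., None, None]
        valid = np.isfinite(nu).all(axis=(-2, -1))
        nu = np.where(valid[..., None, None], nu, 0.0)
        size = (1, smooth_xy, smooth_xy, 1, 1)
        sm_r = uniform_filter(nu.real, size=size, mode="nearest")
        sm_i = uniform_filter(nu.imag, size=size, mode="nearest")
        cnt = uniform_filter(valid.astype(np.float64), size=size[:3], mode="nearest")
        n = sm_r + 1j * sm_i
        n[cnt < 0.5] = np.nan
    return n


def _fold_retardation_deg(n: np.ndarray) -> np.ndarray:
    """Eigenvalue phase split folded into [0, 180]: 2·arccos|tr/(2√det)|."""
    tr = n[..., 0, 0] + n[..., 1, 1]
    det = n[..., 0, 0] * n[..., 1, 1] - n[..., 0, 1] * n[..., 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(tr) / (2 * np.sqrt(np.abs(det)))
    return np.degrees(2 * np.arccos(np.clip(t, 0.0, 1.0)))


def compute_retardation(
    j: JonesVolume, surface: np.ndarray, smooth_xy: int = 3
) -> np.ndarray:
    """Cumulative round-trip retardation (deg) relative to the surface.

    The folded eigenvalue split (0–180°) is unfolded along depth by
    tracking the nearest branch 360k ± φ, so slabs thicker than 90° one-way
    unwrap correctly.  Voxels above the surface are NaN; A-lines without a
    surface (or a singular surface matrix) are fully masked.
    """
    n = _relative_matrices(j, surface, smooth_xy)
    fold = _fold_retardation_deg(n)  # (nz, nx, ny)
    nz = fold.shape[0]
    out = np.full_like(fold, np.nan)
    prev = np.zeros(fold.shape[1:])
    vel = np.zeros_like(prev)  # smoothed depth slope, disambiguates folds
    zz = np.arange(nz)[:, None, None]
    started = zz >= surface[None, :, :]
    for iz in range(nz):
        f = fold[iz]
        pred = prev + vel
        k = np.round(pred / 360.0)
        cand = np.stack([
            (k - 1) * 360 + f, k * 360 - f, k * 360 + f, (k + 1) * 360 - f,
        ])
        pick = np.take_along_axis(
            cand, np.abs(cand - pred).argmin(axis=0)[None], axis=0
        )[0]
        active = started[iz] & np.isfinite(f)
        vel = np.where(active, 0.7 * vel + 0.3 * (pick - prev), vel)
        prev = np.where(active, pick, prev)
        out[iz] = np.where(active, np.abs(prev), np.nan)
    out[:, surface < 0] = np.nan
    return out


def compute_optic_axis(
    j: JonesVolume,
    surface: np.ndarray,
    floor_deg: float = 10.0,
    retardation_deg: np.ndarray | None = None,
    smooth_xy: int = 3,
) -> np.ndarray:
    """Raw (uncalibrated) optic-axis orientation, deg in [0, 180).

    The eigenvector of the surface-relative matrix belonging to the
    leading-phase eigenvalue is mapped to a linear-retarder axis angle via
    its Stokes orientation.  Voxels whose cumulative retardation is within
    ``floor_deg`` of 0 or 360 are masked (axis undefined for δ≈0).  When
    the unwrapped cumulative ``retardation_deg`` is supplied, the 90°
    eigen-order swap past 180° of round-trip retardation is undone.
    """
    n = _relative_matrices(j, surface, smooth_xy)
    tr = n[..., 0, 0] + n[..., 1, 1]
    det = n[..., 0, 0] * n[..., 1, 1] - n[..., 0, 1] * n[..., 1, 0]
    disc = np.sqrt(tr**2 - 4 * det + 0j)
    l1 = (tr + disc) / 2
    l2 = (tr - disc) / 2
    # order so arg(λ1/λ2) ∈ (0, π): λ1 is the fast (leading-phase) eigenvalue
    with np.errstate(divide="ignore", invalid="ignore"):
        swap = np.angle(l1 / l2) < 0
    lead = np.where(swap, l2, l1)
    # eigenvector: (λ − d, c) or (b, λ − a), whichever is better conditioned
    a, b = n[..., 0, 0], n[..., 0, 1]
    c, d = n[..., 1, 0], n[..., 1, 1]
    v1 = np.stack([lead - d, c], axis=-1)
    v2 = np.stack([b, lead - a], axis=-1)
    use2 = np.sum(np.abs(v2) ** 2, -1) > np.sum(np.abs(v1) ** 2, -1)
    v = np.where(use2[..., None], v2, v1)
    q = np.abs(v[..., 0]) ** 2 - np.abs(v[..., 1]) ** 2
    u = 2 * np.real(v[..., 0] * np.conj(v[..., 1]))
    axis = np.degrees(0.5 * np.arctan2(u, q)) % 180.0
    if retardation_deg is not None:
        swap_branch = (retardation_deg % 360.0) > 180.0
        axis = np.where(swap_branch, (axis + 90.0) % 180.0, axis)
    fold = _fold_retardation_deg(n)
    axis[~np.isfinite(fold) | (np.minimum(fold, 360 - fold) < floor_deg)] = np.nan
    zz = np.arange(axis.shape[0])[:, None, None]
    axis[zz < surface[None, :, :]] = np.nan
    axis[:, surface < 0] = np.nan
    return axis


def circular_mean_axis(axis_deg: np.ndarray) -> float:
    """Circular mean of axis angles on the doubled-angle circle (deg mod 180)."""
    a = np.asarray(axis_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    z = np.exp(2j * np.deg2rad(a)).mean()
    return float(np.degrees(0.5 * np.angle(z)) % 180.0)


def _axis_distance(a: float, b: float) -> float:
    """Smallest angular distance on the 180°-periodic axis circle."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def calibrate_optic_axis(
    axis_deg: np.ndarray,
    p0_mask: np.ndarray,
    p45_mask: np.ndarray,
    min_separation_deg: float = 10.0,
) -> tuple[np.ndarray, float, bool]:
    """Reference the axis map to the 0°/45° stabilizer stripes.

    A global offset maps the circular mean of the 0° stripe to 0; the
    chirality (sign) is chosen so the 45° stripe reads +45° rather than
    −45°.  Returns (calibrated axis, offset applied, flipped?).
    """
    m0 = circular_mean_axis(axis_deg[p0_mask])
    m45 = circular_mean_axis(axis_deg[p45_mask])
    if not np.isfinite(m0) or not np.isfinite(m45):
        raise ValueError("stripe ROI contains no valid axis measurements")
    if _axis_distance(m0, m45) < min_separation_deg:
        raise ValueError("calibration stripes are indistinguishable")
    cal = (axis_deg - m0) % 180.0
    sep = (m45 - m0) % 180.0
    flipped = _axis_distance(sep, 45.0) > _axis_distance(sep, 135.0)
    if flipped:
        cal = (-cal) % 180.0
    return cal, m0, flipped


def compute_dopu(j: JonesVolume, kernel: tuple[int, int, int] = (3, 9, 1)) -> np.ndarray:
    """Degree of polarization uniformity of the H-input response state.

    DOPU = ‖⟨(Q, U, V)/I⟩_kernel‖ ∈ [0, 1]: 1 for a spatially uniform
    polarization state, → 1/√n for isotropically random states in an
    n-voxel kernel.
    """
    if any(k > s for k, s in zip(kernel, j.shape)):
        raise ValueError("DOPU kernel larger than the volume")
    h = j.j[..., 0, 0]
    v = j.j[..., 1, 0]
    i = np.abs(h) ** 2 + np.abs(v) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (np.abs(h) ** 2 - np.abs(v) ** 2) / i
        u = 2 * np.real(h * np.conj(v)) / i
        w = 2 * np.imag(h * np.conj(v)) / i
    comps = []
    for s in (q, u, w):
        s = np.where(np.isfinite(s), s, 0.0)
        comps.append(uniform_filter(s, size=kernel, mode="nearest"))
    return np.clip(np.sqrt(sum(c**2 for c in comps)), 0.0, 1.0)


def local_retardance(
    retardation_deg: np.ndarray, dz_um: float, smooth_px: int = 7
) -> np.ndarray:
    """One-way local retardance (deg/µm) from the cumulative map's depth slope."""
    r = np.where(np.isfinite(retardation_deg), retardation_deg, 0.0)
    r = uniform_filter1d(r, size=smooth_px, axis=0, mode="nearest")
    slope = np.gradient(r, axis=0) / dz_um  # round-trip deg/µm
    return np.abs(slope) / 2.0


def compute_bwoa(
    retardation_deg: np.ndarray,
    axis_deg: np.ndarray,
    reflectance_db: np.ndarray,
    validity: np.ndarray,
    dz_um: float,
    params: ReconParams | None = None,
    noise_floor_db: float = 0.0,
) -> np.ndarray:
    """Birefringence-weighted optic axis composite as RGB in [0, 1].

    Hue encodes the (cyclic) axis orientation, saturation the local
    retardance up to a display cap, and value the reflectance; value is
    zeroed outside the validity mask so unreliable voxels render black.
    """
    p = params or ReconParams()
    hue = np.where(np.isfinite(axis_deg), axis_deg, 0.0) % 180.0 / 180.0
    sat = np.clip(local_retardance(retardation_deg, dz_um) / p.bwoa_sat_cap_deg_um, 0, 1)
    sat = np.where(np.isfinite(axis_deg), sat, 0.0)
    lo, hi = p.bwoa_value_range_db
    val = np.clip((reflectance_db - noise_floor_db - lo) / (hi - lo), 0, 1)
    val = np.where(validity, val, 0.0)
    return hsv_to_rgb(np.stack([hue, sat, val], axis=-1))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def reconstruct(
    raw: RawAcquisition,
    params: ReconParams | None = None,
    stripe_masks: "tuple[np.ndarray, np.ndarray] | None" = None,
    repeat: int = 0,
) -> ChannelSet:
    """Run the full channel reconstruction on one repeat of an acquisition.

    ``stripe_masks`` = (P0 voxels, P45 voxels) enables optic-axis
    calibration; without it the raw instrument-frame axis is returned.
    """
    p = params or ReconParams()
    j = assemble_jones(raw, repeat=repeat)
    refl = compute_reflectance(j, floor_db=None)
    floor = p.noise_floor_db if p.noise_floor_db is not None else estimate_noise_floor(refl)
    surface = detect_surface(refl, floor, p.surface_margin_db, p.surface_run)

    lin = 10 ** (refl / 10)
    atten = compute_attenuation(
        lin,
        j.pitch_axial_um,
        tail_mask=p.atten_tail_mask,
        noise_level=1.1 * 10 ** (floor / 10),  # mean noise power (floor is a median)
        tail_correction=p.atten_tail_correction,
    )
    ret = compute_retardation(j, surface, smooth_xy=p.jones_smooth_xy)
    axis = compute_optic_axis(
        j, surface, floor_deg=p.axis_floor_deg, retardation_deg=ret,
        smooth_xy=p.jones_smooth_xy,
    )
    offset = None
    if stripe_masks is not None:
        axis, offset, _ = calibrate_optic_axis(axis, *stripe_masks)
    dopu = compute_dopu(j, kernel=p.dopu_kernel)

    zz = np.arange(refl.shape[0])[:, None, None]
    below_surface = (zz >= surface[None, :, :]) & (surface >= 0)[None, :, :]
    validity = below_surface & (dopu >= p.dopu_min) & (refl >= floor + p.valid_margin_db)
    bwoa = compute_bwoa(ret, axis, refl, validity, j.pitch_axial_um, p, floor)

    return ChannelSet(
        reflectance_db=refl.astype(np.float32),
        attenuation_mm=atten.astype(np.float32),
        retardation_deg=ret.astype(np.float32),
        axis_deg=axis.astype(np.float32),
        dopu=dopu.astype(np.float32),
        bwoa_rgb=bwoa.astype(np.float32),
        validity=validity,
        surface=surface,
        pitch_axial_um=j.pitch_axial_um,
        pitch_lateral_um=j.pitch_lateral_um,
        noise_floor_db=floor,
        axis_calibration_offset_deg=offset,
    )
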