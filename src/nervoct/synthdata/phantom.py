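"""Ground-truth digital nerve phantom.

The phantom mimics the imaging scene of the stimulation study: a sciatic
nerve cross-section with three fascicles (labeled L/C/R by proximity to the
stimulation lead), a weakly birefringent epineurium, intra-/epineurial
vessels running along the nerve, and the two birefringent calibration
stripes built into the nerve stabilizer whose optic axes are 0° and 45°.

All per-voxel maps share one (z, x, y) grid: z is depth into tissue
(index 0 at the top of the field of view), x is the fast lateral scan axis
(the cross-section), y the slow axis (along the nerve).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FascicleSpec",
    "VesselSpec",
    "StripeSpec",
    "NerveGeometry",
    "PhantomTruth",
    "build_nerve_truth",
    "default_geometry",
    "small_geometry",
]

FASCICLE_LABELS = {"L": 1, "C": 2, "R": 3}
STRIPE_LABELS = {"P0": 1, "P45": 2}


@dataclass(frozen=True)
class FascicleSpec:
    """Elliptical fascicle in the (z, x) cross-section, extruded along y.

    delta is the one-way birefringent retardance per unit depth (deg/µm),
    theta the optic-axis orientation (deg, mod 180), mu the attenuation
    coefficient (1/µm).
    """

    center_z: float
    center_x: float
    semi_z: float
    semi_x: float
    delta_deg_um: float
    theta_deg: float
    mu_per_um: float
    backscatter: float = 1.0


@dataclass(frozen=True)
class VesselSpec:
    """Straight tube along y at fixed (z, x), with optional lateral wiggle."""

    center_z: float
    center_x: float
    radius_um: float
    rho: float = 0.3  # inter-repeat speckle correlation; 1 = static tissue
    wiggle_px: float = 0.0  # sinusoidal x-excursion amplitude along y
    wiggle_period: float = 120.0  # in y frames


@dataclass(frozen=True)
class StripeSpec:
    """Calibration-phantom stripe: constant axis, constant retardance."""

    x_range: tuple[int, int]  # [lo, hi) pixel columns
    theta_deg: float
    delta_deg_um: float = 0.40
    mu_per_um: float = 0.0015
    backscatter: float = 0.9


@dataclass(frozen=True)
class NerveGeometry:
    """Full phantom layout plus tissue optical parameters."""

    shape: tuple[int, int, int] = (256, 200, 250)  # (nz, nx, ny)
    pitch_axial_um: float = 3.5
    pitch_lateral_um: float = 10.0
    surface_z: int = 20
    # epineurium envelope (ellipse enclosing the fascicles)
    epi_center_z: float = 88.0
    epi_center_x: float = 100.0
    epi_semi_z: float = 68.0
    epi_semi_x: float = 72.0
    epi_delta_deg_um: float = 0.02
    epi_theta_deg: float = 0.0
    epi_mu_per_um: float = 0.0022
    epi_backscatter: float = 0.8
    epi_depol: float = 0.0
    # multiple-scattering depolarization band in the deep epineurium: voxels
    # deeper than center + frac·semi_z get this depolarization fraction
    deep_depol: float = 0.3
    deep_depol_frac: float = 0.6
    fascicles: dict[str, FascicleSpec] = field(
        default_factory=lambda: {
            "L": FascicleSpec(88, 56, 26, 22, 0.22, 25.0, 0.0026),
            "C": FascicleSpec(82, 100, 28, 23, 0.28, 90.0, 0.0030),
            "R": FascicleSpec(88, 144, 26, 22, 0.33, 140.0, 0.0035),
        }
    )
    stripes: dict[str, StripeSpec] = field(
        default_factory=lambda: {
            "P0": StripeSpec((4, 22), 0.0),
            "P45": StripeSpec((178, 196), 45.0),
        }
    )
    stripe_depth_px: int = 120
    vessels: tuple[VesselSpec, ...] = (
        VesselSpec(34, 78, 32.0, 0.3, wiggle_px=3.0),
        VesselSpec(38, 118, 26.0, 0.3, wiggle_px=2.0, wiggle_period=90.0),
        VesselSpec(42, 60, 22.0, 0.4),
    )
    backscatter_texture_sd: float = 0.15  # lognormal sd of backscatter texture
    # tissue bed the nerve and stabilizer rest on (muscle/connective tissue):
    # fills every tissue/stripe column below the structure so the OCT decay
    # continues to the bottom of the grid instead of ending in air
    bed_backscatter: float = 0.7
    bed_mu_per_um: float = 0.0025
    bed_depol: float = 0.0
    # couple backscatter amplitude to the scattering coefficient (b = µ/µ_ref),
    # the standard single-scattering model in which a fixed fraction of the
    # attenuated light is backscattered; depth-resolved attenuation
    # estimation from intensity assumes exactly this
    couple_backscatter: bool = True
    backscatter_ref_mu: float = 0.003


@dataclass
class PhantomTruth:
    """Per-voxel ground truth on a (nz, nx, ny) grid."""

    backscatter: np.ndarray  # unitless >= 0
    mu: np.ndarray  # attenuation, 1/µm
    delta: np.ndarray  # one-way retardance per depth, deg/µm
    theta: np.ndarray  # optic-axis orientation, deg in [0, 180)
    depol: np.ndarray  # depolarization fraction, 0..1
    rho: np.ndarray  # inter-repeat speckle correlation, 0..1 (1 = static)
    fascicle_labels: np.ndarray  # uint8: 0 none, 1 L, 2 C, 3 R
    stripe_labels: np.ndarray  # uint8: 0 none, 1 P0, 2 P45
    geometry: NerveGeometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.backscatter.shape

    def fascicle_mask(self, label: str) -> np.ndarray:
        return self.fascicle_labels == FASCICLE_LABELS[label]

    def stripe_mask(self, label: str) -> np.ndarray:
        return self.stripe_labels == STRIPE_LABELS[label]

    def vessel_mask(self) -> np.ndarray:
        return self.rho < 1.0


def default_geometry() -> NerveGeometry:
    """The full-size phantom layout (≈0.9 mm deep × 2 mm × 2.5 mm)."""
    return NerveGeometry()


def small_geometry(ny: int = 24) -> NerveGeometry:
    """A half-scale desk phantom for fast experimentation and unit tests."""
    g = NerveGeometry()
    return replace(
        g,
        shape=(160, 100, ny),
        epi_center_z=62.0,
        epi_center_x=50.0,
        epi_semi_z=44.0,
        epi_semi_x=36.0,
        fascicles={
            "L": FascicleSpec(62, 28, 17, 11, 0.22, 25.0, 0.0026),
            "C": FascicleSpec(58, 50, 18, 11, 0.28, 90.0, 0.0030),
            "R": FascicleSpec(62, 72, 17, 11, 0.33, 140.0, 0.0035),
        },
        stripes={
            "P0": StripeSpec((2, 11), 0.0),
            "P45": StripeSpec((89, 98), 45.0),
        },
        stripe_depth_px=100,
        vessels=(
            VesselSpec(27, 39, 28.0, 0.3, wiggle_px=2.0),
            VesselSpec(30, 59, 22.0, 0.3, wiggle_px=1.5, wiggle_period=60.0),
        ),
    )


def _ellipse_mask(
    nz: int, nx: int, cz: float, cx: float, az: float, ax: float
) -> np.ndarray:
    zz, xx = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    return ((zz - cz) / az) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def build_nerve_truth(geometry: NerveGeometry | None = None, seed: int = 0) -> PhantomTruth:
    """Rasterize a :class:`NerveGeometry` into per-voxel truth maps.

    Deterministic for a fixed seed (the seed drives only the backscatter
    speckle-free texture).  Raises ``ValueError`` for overlapping fascicle
    ellipses or stripes that intersect the tissue envelope.
    """
    geo = geometry or default_geometry()
    nz, nx, ny = geo.shape
    z0 = geo.surface_z

    # --- 2D cross-section masks -------------------------------------------
    epi2d = _ellipse_mask(nz, nx, geo.epi_center_z, geo.epi_center_x, geo.epi_semi_z, geo.epi_semi_x)
    epi2d[:z0, :] = False
    fasc2d: dict[str, np.ndarray] = {}
    for name, f in geo.fascicles.items():
        m = _ellipse_mask(nz, nx, f.center_z, f.center_x, f.semi_z, f.semi_x)
        m[:z0, :] = False
        if not np.all(epi2d[m]):
            raise ValueError(f"fascicle {name} extends outside the epineurium envelope")
        fasc2d[name] = m
    names = list(fasc2d)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(fasc2d[a] & fasc2d[b]):
                raise ValueError(f"fascicle ellipses {a} and {b} overlap")

    stripe2d: dict[str, np.ndarray] = {}
    for name, s in geo.stripes.items():
        m = np.zeros((nz, nx), dtype=bool)
        lo, hi = s.x_range
        m[z0 : z0 + geo.stripe_depth_px, lo:hi] = True
        if np.any(m & epi2d):
            raise ValueError(f"stripe {name} overlaps the tissue envelope")
        stripe2d[name] = m

    # --- fill the 2D parameter maps ---------------------------------------
    def _zeros() -> np.ndarray:
        return np.zeros((nz, nx), dtype=np.float32)

    back2d, mu2d, delta2d, theta2d, depol2d = (_zeros() for _ in range(5))
    back2d[epi2d] = geo.epi_backscatter
    mu2d[epi2d] = geo.epi_mu_per_um
    delta2d[epi2d] = geo.epi_delta_deg_um
    theta2d[epi2d] = geo.epi_theta_deg % 180.0
    depol2d[epi2d] = geo.epi_depol
    if geo.deep_depol > 0:
        zz_ = np.arange(nz)[:, None]
        deep = epi2d & (zz_ > geo.epi_center_z + geo.deep_depol_frac * geo.epi_semi_z)
        depol2d[deep] = geo.deep_depol
    lab2d = np.zeros((nz, nx), dtype=np.uint8)
    for name, f in geo.fascicles.items():
        m = fasc2d[name]
        back2d[m] = f.backscatter
        mu2d[m] = f.mu_per_um
        delta2d[m] = f.delta_deg_um
        theta2d[m] = f.theta_deg % 180.0
        depol2d[m] = 0.0
        lab2d[m] = FASCICLE_LABELS[name]
    strip2d = np.zeros((nz, nx), dtype=np.uint8)
    for name, s in geo.stripes.items():
        m = stripe2d[name]
        back2d[m] = s.backscatter
        mu2d[m] = s.mu_per_um
        delta2d[m] = s.delta_deg_um
        theta2d[m] = s.theta_deg % 180.0
        strip2d[m] = STRIPE_LABELS[name]

    if geo.couple_backscatter:
        back2d = np.where(mu2d > 0, mu2d / geo.backscatter_ref_mu, 0.0).astype(np.float32)

    # tissue bed below the nerve / stabilizer stripes
    if geo.bed_backscatter > 0:
        occupied = epi2d | np.logical_or.reduce(list(stripe2d.values()))
        has_struct = occupied.any(axis=0)
        bottom = nz - 1 - np.argmax(occupied[::-1], axis=0)
        zz_ = np.arange(nz)[:, None]
        bed = has_struct[None, :] & (zz_ > bottom[None, :]) & ~occupied
        mu2d[bed] = geo.bed_mu_per_um
        back2d[bed] = (
            geo.bed_mu_per_um / geo.backscatter_ref_mu
            if geo.couple_backscatter
            else geo.bed_backscatter
        )
        depol2d[bed] = geo.bed_depol

    # --- extrude along y ---------------------------------------------------
    def _ext(a: np.ndarray) -> np.ndarray:
        return np.repeat(a[:, :, None], ny, axis=2)

    truth = PhantomTruth(
        backscatter=_ext(back2d),
        mu=_ext(mu2d),
        delta=_ext(delta2d),
        theta=_ext(theta2d),
        depol=_ext(depol2d),
        rho=np.ones((nz, nx, ny), dtype=np.float32),
        fascicle_labels=_ext(lab2d),
        stripe_labels=_ext(strip2d),
        geometry=geo,
    )

    # --- vessels: tubes along y with optional lateral wiggle ---------------
    r_px_z = lambda v: v.radius_um / geo.pitch_axial_um
    r_px_x = lambda v: v.radius_um / geo.pitch_lateral_um
    zz, xx = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
    for v in geo.vessels:
        for iy in range(ny):
            cx = v.center_x + v.wiggle_px * np.sin(2 * np.pi * iy / v.wiggle_period)
            m = ((zz - v.center_z) / r_px_z(v)) ** 2 + ((xx - cx) / r_px_x(v)) ** 2 <= 1.0
            truth.rho[:, :, iy][m] = v.rho

    # mild multiplicative backscatter texture (deterministic per seed)
    if geo.backscatter_texture_sd > 0:
        rng = np.random.default_rng(seed)
        tex = rng.lognormal(mean=0.0, sigma=geo.backscatter_texture_sd, size=(nz, nx, ny))
        truth.backscatter *= tex.astype(np.float32)

    return truth
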