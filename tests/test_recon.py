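"""Channel reconstruction: Jones assembly, scalar channels, polarimetry."""

import numpy as np
import pytest

from nervoct.recon import (
    JonesVolume,
    ReconParams,
    assemble_jones,
    calibrate_optic_axis,
    circular_mean_axis,
    compute_attenuation,
    compute_bwoa,
    compute_dopu,
    compute_optic_axis,
    compute_reflectance,
    compute_retardation,
    detect_surface,
    reconstruct,
)
from nervoct.recovery import evaluate_recovery
from nervoct.synthdata import (
    H45_INPUT_STATES,
    AcquisitionConfig,
    random_unitary,
    round_trip_matrices,
    simulate_tomogram,
)

from .test_tomogram import uniform_truth


def _slab_acquisition(delta=0.3, theta=30.0, nz=100, **cfg_kw):
    t = uniform_truth(nz=nz, nx=16, ny=8, surface=5, delta=delta, theta=theta)
    kw = dict(repeats=1, snr_db=None, seed=0, apply_psf=False)
    kw.update(cfg_kw)
    return t, simulate_tomogram(t, AcquisitionConfig(**kw))


class TestAssembleJones:
    def test_identity_medium_gives_scalar_identity(self):
        t, raw = _slab_acquisition(delta=0.0)
        j = assemble_jones(raw).j
        below = j[10:]
        # off-diagonals vanish, diagonals equal
        assert np.abs(below[..., 0, 1]).max() < 1e-6 * np.abs(below[..., 0, 0]).max()
        assert np.allclose(below[..., 0, 0], below[..., 1, 1], atol=1e-6)

    def test_matches_forward_model_matrix(self):
        """Noise-free measured J equals the simulator's own matrix product
        to 1e-6 relative, up to the common speckle scalar."""
        t, raw = _slab_acquisition(delta=0.3, theta=30.0)
        cfg = raw.config
        j = assemble_jones(raw).j.astype(np.complex128)
        m = round_trip_matrices(t, cfg).astype(np.complex128)
        zi, xi, yi = 40, 7, 3
        scale = j[zi, xi, yi, 0, 0] / m[zi, xi, yi, 0, 0]
        assert np.allclose(j[zi, xi, yi], m[zi, xi, yi] * scale, rtol=1e-5)

    def test_input_state_basis_invariance(self):
        """Swapping the two input-state columns (with their A-line labels)
        leaves the assembled matrix unchanged."""
        t, raw1 = _slab_acquisition(delta=0.25, theta=70.0, input_states=H45_INPUT_STATES)
        swapped = H45_INPUT_STATES[:, ::-1].copy()
        _, raw2 = _slab_acquisition(delta=0.25, theta=70.0, input_states=swapped)
        j1 = assemble_jones(raw1).j
        j2 = assemble_jones(raw2).j
        assert np.allclose(j1[10:], j2[10:], atol=1e-5 * np.abs(j1[10:]).max())


class TestReflectance:
    def test_doubling_amplitude_adds_6db(self, rng):
        j = JonesVolume(rng.normal(size=(4, 4, 4, 2, 2)) + 0j, 1.0, 1.0)
        j2 = JonesVolume(2 * j.j, 1.0, 1.0)
        d = compute_reflectance(j2, floor_db=-80) - compute_reflectance(j, floor_db=-80)
        assert np.allclose(d, 20 * np.log10(2), atol=1e-9)

    def test_zero_voxel_hits_floor_not_minus_inf(self):
        j = JonesVolume(np.zeros((3, 3, 3, 2, 2), complex), 1.0, 1.0)
        refl = compute_reflectance(j, floor_db=-55.0)
        assert np.all(refl == -55.0)

    def test_mean_depth_slope_is_minus_two_mu(self):
        mu = 0.004
        t = uniform_truth(nz=120, nx=64, ny=32, mu=mu)
        raw = simulate_tomogram(t, AcquisitionConfig(repeats=1, snr_db=None, seed=3, apply_psf=False))
        refl = compute_reflectance(assemble_jones(raw))
        zs = np.arange(10, 110)
        # dB per pixel: −2µ·dz·(10/ln10)
        prof = 10 * np.log10((10 ** (refl / 10)).mean(axis=(1, 2)))
        slope = np.polyfit(zs, prof[zs], 1)[0]
        expected = -2 * mu * t.geometry.pitch_axial_um * 10 / np.log(10)
        assert slope == pytest.approx(expected, rel=0.05)


class TestSurfaceDetection:
    def test_flat_surface_found(self):
        refl = np.full((50, 8, 8), -60.0)
        refl[12:] = -20.0
        surf = detect_surface(refl, noise_floor_db=-60.0)
        assert np.all(surf == 12)

    def test_no_surface_flagged(self):
        refl = np.full((50, 4, 4), -60.0)
        assert np.all(detect_surface(refl, noise_floor_db=-60.0) == -1)

    def test_single_speckle_spike_ignored(self):
        refl = np.full((50, 1, 1), -60.0)
        refl[5, 0, 0] = -10.0  # isolated spike, shorter than the 3-px run
        refl[20:, 0, 0] = -20.0
        assert detect_surface(refl, noise_floor_db=-60.0)[0, 0] == 20


class TestAttenuation:
    def test_geometric_decay_oracle(self):
        """I halves per pixel, Δz=1 → µ̂ = ln2/2 at every valid depth."""
        i = (2.0 ** -np.arange(60))[:, None]
        mu = compute_attenuation(i, dz_um=1000.0, tail_mask=5)
        valid = np.isfinite(mu[:, 0])
        assert np.allclose(mu[valid, 0], np.log(2) / 2, rtol=1e-9)

    def test_constant_intensity_closed_form(self):
        """Uncorrected estimator on a constant A-line of length N."""
        n = 50
        i = np.ones((n, 1))
        mu = compute_attenuation(i, dz_um=1000.0, tail_mask=0, tail_correction=False)
        ks = np.arange(n - 1)
        expected = np.log(1 + 1 / (n - 1 - ks)) / 2
        assert np.allclose(mu[:-1, 0], expected, rtol=1e-9)

    def test_scale_invariance(self, rng):
        i = rng.exponential(size=(80, 6)) * np.exp(-0.05 * np.arange(80))[:, None]
        a = compute_attenuation(i, dz_um=3.5)
        b = compute_attenuation(7.3 * i, dz_um=3.5)
        assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)], rtol=1e-9)

    def test_zero_tail_masked_not_raised(self):
        i = np.zeros((30, 2))
        i[5, 0] = 1.0
        mu = compute_attenuation(i, dz_um=3.5, tail_mask=0)
        assert np.isnan(mu[5, 0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_attenuation(-np.ones((5, 1)), dz_um=3.5)


class TestRetardation:
    def test_uniform_slab_doubles_one_way_retardance(self):
        """One-way 30° slab → 60° round trip at the slab bottom, ±1°."""
        t, raw = _slab_acquisition(delta=0.3, theta=30.0)
        ch = reconstruct(raw, ReconParams(dopu_kernel=(3, 3, 1)))
        dz = t.geometry.pitch_axial_um
        zb = 60
        expected = 2 * 0.3 * dz * (zb - 5)
        assert np.nanmean(ch.retardation_deg[zb]) == pytest.approx(expected, abs=1.0)

    def test_zero_birefringence_reads_zero(self):
        t, raw = _slab_acquisition(delta=0.0)
        ch = reconstruct(raw, ReconParams(dopu_kernel=(3, 3, 1)))
        below = ch.retardation_deg[10:80]
        assert np.nanmax(np.abs(below)) < 1.0

    def test_stacked_same_axis_slabs_add(self):
        """One-way 20° then 10° on a shared axis → 60° round trip total."""
        t = uniform_truth(nz=100, nx=16, ny=8, surface=5)
        dz = t.geometry.pitch_axial_um
        # slab 1: z 5..55 accumulates 20° one way; slab 2: z 55..95 adds 10°
        t.delta[5:55] = 20.0 / (50 * dz)
        t.delta[55:95] = 10.0 / (40 * dz)
        t.theta[5:] = 40.0
        raw = simulate_tomogram(t, AcquisitionConfig(repeats=1, snr_db=None, seed=0, apply_psf=False))
        ch = reconstruct(raw, ReconParams(dopu_kernel=(3, 3, 1)))
        assert np.nanmean(ch.retardation_deg[94]) == pytest.approx(60.0, abs=1.5)

    def test_unfolds_beyond_180_degrees(self):
        t, raw = _slab_acquisition(delta=0.35, theta=20.0, nz=140)
        ch = reconstruct(raw, ReconParams(dopu_kernel=(3, 3, 1)))
        dz = t.geometry.pitch_axial_um
        zb = 130
        expected = 2 * 0.35 * dz * (zb - 5)  # ≈ 306°
        assert expected > 180
        assert np.nanmean(ch.retardation_deg[zb]) == pytest.approx(expected, rel=0.02)

    def test_system_unitary_invariance(self):
        """Retardation is identical under any detection unitary (noise-free)."""
        t, raw1 = _slab_acquisition(delta=0.3, theta=30.0)
        _, raw2 = _slab_acquisition(delta=0.3, theta=30.0, system_unitary=random_unitary(3))
        r1 = compute_retardation(assemble_jones(raw1), np.full((16, 8), 5))
        r2 = compute_retardation(assemble_jones(raw2), np.full((16, 8), 5))
        assert np.allclose(r1[10:90], r2[10:90], atol=1e-3)


class TestOpticAxis:
    def test_axis_recovered_in_identity_frame(self):
        t, raw = _slab_acquisition(delta=0.3, theta=0.0)
        axis = compute_optic_axis(assemble_jones(raw), np.full((16, 8), 5))
        mid = axis[30:60]
        d = np.minimum(np.abs(mid % 180), 180 - np.abs(mid % 180))
        assert np.nanmax(d) < 2.0

    @pytest.mark.parametrize("shift", [30.0, 75.0])
    def test_equivariance_under_axis_rotation(self, shift):
        _, raw1 = _slab_acquisition(delta=0.3, theta=20.0)
        _, raw2 = _slab_acquisition(delta=0.3, theta=20.0 + shift)
        s = np.full((16, 8), 5)
        a1 = compute_optic_axis(assemble_jones(raw1), s)
        a2 = compute_optic_axis(assemble_jones(raw2), s)
        d = (np.nanmean(a2[30:60]) - np.nanmean(a1[30:60])) % 180
        assert d == pytest.approx(shift, abs=1.0)

    def test_mod_180_identity(self):
        _, raw1 = _slab_acquisition(delta=0.3, theta=170.0)
        _, raw2 = _slab_acquisition(delta=0.3, theta=-10.0)
        s = np.full((16, 8), 5)
        a1 = compute_optic_axis(assemble_jones(raw1), s)
        a2 = compute_optic_axis(assemble_jones(raw2), s)
        assert np.nanmean(a1[30:60]) == pytest.approx(np.nanmean(a2[30:60]), abs=1e-3)

    def test_axis_masked_where_retardance_below_floor(self):
        t, raw = _slab_acquisition(delta=0.0)
        axis = compute_optic_axis(assemble_jones(raw), np.full((16, 8), 5))
        assert np.all(np.isnan(axis))


class TestCalibration:
    def test_circular_mean_folds_at_180(self):
        assert circular_mean_axis(np.array([10.0, 170.0])) == pytest.approx(0.0, abs=1e-9)
        assert circular_mean_axis(np.array([80.0, 100.0])) == pytest.approx(90.0)

    def test_calibration_contract_on_phantom(self, phantom_truth, study_channels):
        """With an arbitrary unitary and frame offset, calibrated stripes
        read 0° and 45° within 2°."""
        from nervoct.recovery import stripe_calibration_masks

        p0, p45 = stripe_calibration_masks(phantom_truth, study_channels)
        m0 = circular_mean_axis(study_channels.axis_deg[p0])
        m45 = circular_mean_axis(study_channels.axis_deg[p45])
        assert min(m0, 180 - m0) == pytest.approx(0.0, abs=2.0)
        assert m45 == pytest.approx(45.0, abs=2.0)

    def test_idempotent_on_calibrated_volume(self, rng):
        axis = rng.uniform(0, 180, size=(20, 20, 4))
        axis[:5] = 0.0
        axis[5:8] = 45.0
        p0 = np.zeros_like(axis, bool)
        p0[:5] = True
        p45 = np.zeros_like(axis, bool)
        p45[5:8] = True
        cal, off, flip = calibrate_optic_axis(axis, p0, p45)
        assert off == pytest.approx(0.0, abs=1e-6)
        assert not flip
        assert np.allclose(cal % 180, axis % 180, atol=1e-6)

    def test_chirality_flip_detected(self, rng):
        axis = rng.uniform(0, 180, size=(20, 10, 2))
        axis[:5] = 10.0  # P0 reads 10 → offset 10
        axis[5:8] = (10.0 - 45.0) % 180  # P45 reads −45 relative → flipped
        p0 = np.zeros_like(axis, bool); p0[:5] = True
        p45 = np.zeros_like(axis, bool); p45[5:8] = True
        cal, off, flip = calibrate_optic_axis(axis, p0, p45)
        assert flip
        assert circular_mean_axis(cal[p45]) == pytest.approx(45.0, abs=1e-6)

    def test_indistinguishable_stripes_fail(self):
        axis = np.full((10, 10, 2), 30.0)
        p0 = np.zeros_like(axis, bool); p0[:3] = True
        p45 = np.zeros_like(axis, bool); p45[3:6] = True
        with pytest.raises(ValueError, match="indistinguishable"):
            calibrate_optic_axis(axis, p0, p45)


class TestDopu:
    def test_uniform_state_scores_one(self):
        j = np.zeros((8, 12, 6, 2, 2), complex)
        j[..., 0, 0] = 1.0
        j[..., 1, 0] = 0.5j
        dopu = compute_dopu(JonesVolume(j, 1.0, 1.0), kernel=(3, 5, 1))
        assert np.allclose(dopu, 1.0, atol=1e-9)

    def test_random_states_scale_as_inverse_sqrt_n(self, rng):
        """Isotropic random Stokes directions in an n-voxel kernel give
        E[DOPU] ≈ 1/√n (random-walk resultant), checked within ±20%."""
        n = 81
        j = np.zeros((9, 90, 90, 2, 2), complex)
        j[..., 0, 0] = rng.normal(size=(9, 90, 90)) + 1j * rng.normal(size=(9, 90, 90))
        j[..., 1, 0] = rng.normal(size=(9, 90, 90)) + 1j * rng.normal(size=(9, 90, 90))
        dopu = compute_dopu(JonesVolume(j, 1.0, 1.0), kernel=(1, 9, 9))
        assert dopu[4, 20:70, 20:70].mean() == pytest.approx(1 / np.sqrt(n), rel=0.20)

    def test_depolarized_region_scores_lower(self, phantom_truth, study_channels):
        deep = phantom_truth.depol > 0
        clean = phantom_truth.fascicle_labels > 0
        assert study_channels.dopu[deep].mean() < study_channels.dopu[clean].mean() - 0.1

    def test_oversized_kernel_rejected(self):
        j = JonesVolume(np.zeros((4, 4, 2, 2, 2), complex), 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_dopu(j, kernel=(9, 9, 9))


class TestBwoa:
    def _channels(self, ret, axis, refl, valid):
        return compute_bwoa(ret, axis, refl, valid, dz_um=3.5, noise_floor_db=-60.0)

    def test_zero_retardance_is_gray(self):
        shape = (20, 6, 4)
        rgb = self._channels(
            np.zeros(shape), np.full(shape, 30.0), np.full(shape, -30.0), np.ones(shape, bool)
        )
        assert np.allclose(rgb[..., 0], rgb[..., 1], atol=1e-6)
        assert np.allclose(rgb[..., 1], rgb[..., 2], atol=1e-6)

    def test_axes_0_and_180_share_hue(self):
        shape = (8, 4, 2)
        ret = np.tile(np.linspace(0, 120, 8)[:, None, None], (1, 4, 2))
        a = self._channels(ret, np.zeros(shape), np.full(shape, -30.0), np.ones(shape, bool))
        b = self._channels(ret, np.full(shape, 180.0), np.full(shape, -30.0), np.ones(shape, bool))
        assert np.allclose(a, b, atol=1e-6)

    def test_saturation_monotone_in_local_retardance(self):
        shape = (40, 4, 2)
        axis = np.full(shape, 90.0)
        refl = np.full(shape, -30.0)
        valid = np.ones(shape, bool)
        sats = []
        for slope in (0.2, 0.6, 1.2):  # deg/px round trip
            ret = np.tile((slope * np.arange(40))[:, None, None], (1, 4, 2))
            rgb = self._channels(ret, axis, refl, valid)
            mx, mn = rgb[20].max(-1), rgb[20].min(-1)
            sats.append(np.mean((mx - mn) / np.maximum(mx, 1e-12)))
        assert sats[0] < sats[1] <= sats[2] + 1e-9

    def test_value_zero_outside_mask(self):
        shape = (10, 4, 2)
        valid = np.zeros(shape, bool)
        rgb = self._channels(
            np.full(shape, 50.0), np.full(shape, 10.0), np.full(shape, -10.0), valid
        )
        assert np.all(rgb == 0.0)


class TestRecoveryInvariants:
    def test_noise_free_parameter_recovery(self, phantom_truth, clean_channels):
        df = evaluate_recovery(phantom_truth, clean_channels)
        fa = df[df.kind == "fascicle"]
        assert np.all(np.abs(fa.ret_ratio - 1) < 0.05)
        assert np.all(np.abs(fa.mu_ratio - 1) < 0.10)
        assert np.sqrt((fa.axis_err_deg**2).mean()) < 3.0

    def test_no_nan_inside_validity_mask(self, study_channels):
        v = study_channels.validity
        assert np.isfinite(study_channels.reflectance_db[v]).all()
        assert np.isfinite(study_channels.retardation_deg[v]).all()
        assert np.isfinite(study_channels.dopu[v]).all()
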