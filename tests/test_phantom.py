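"""Digital vessel phantom, coil maps, and acquisition simulation."""

import numpy as np
import pytest

import wavetof as wt
from wavetof.gradients import compute_moments, flow_phase_series, synthesize_waveforms
from wavetof.trajectory import trajectory_from_waveform

from conftest import nrmse


class TestVesselPhantom:
    def test_determinism(self):
        spec = wt.PhantomSpec(dims=(32, 32, 16), seed=11)
        a, b = wt.make_vessel_phantom(spec), wt.make_vessel_phantom(spec)
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.velocity, b.velocity)

    def test_no_vessels(self):
        spec = wt.PhantomSpec(dims=(32, 32, 16), n_vessels=0)
        ph = wt.make_vessel_phantom(spec)
        assert not ph.vessel_labels.any()
        assert np.all(ph.velocity == 0)

    def test_velocity_zero_outside_vessels(self, default_phantom):
        outside = ~default_phantom.vessel_labels
        assert np.all(default_phantom.velocity[outside] == 0)
        inside_speed = np.linalg.norm(
            default_phantom.velocity[default_phantom.vessel_labels], axis=1
        )
        lo, hi = default_phantom.spec.flow_speed_mm_s
        assert np.all((inside_speed >= lo - 1e-9) & (inside_speed <= hi + 1e-9))

    def test_volume_fraction_matches_tube_geometry(self, default_phantom):
        """Vessel voxel count within [0.5x, 2x] of sum(pi r^2 L) / V."""
        spec = default_phantom.spec
        voxel_vol = np.prod(np.array(spec.fov_mm) / np.array(spec.dims))
        analytic = sum(np.pi * r**2 * L for r, L in default_phantom.vessel_info)
        measured = default_phantom.vessel_labels.sum() * voxel_vol
        assert 0.5 * analytic <= measured <= 2.0 * analytic

    def test_contrast_and_positivity(self, default_phantom):
        spec = default_phantom.spec
        assert np.all(default_phantom.magnitude >= 0)
        v_mean = default_phantom.magnitude[default_phantom.vessel_labels].mean()
        bg = default_phantom.support & ~default_phantom.vessel_labels
        # tapered tubes carry partial-volume edges, so the labelled-vessel
        # mean sits between the blend midpoint and full vessel intensity
        assert 0.7 * spec.vessel_intensity <= v_mean <= spec.vessel_intensity
        assert default_phantom.magnitude[bg].mean() < 0.6 * v_mean


class TestCoilMaps:
    def test_single_coil_uniform(self):
        dims = (16, 16, 16)
        support = np.ones(dims, bool)
        maps = wt.make_coil_maps(1, dims, support)
        assert np.allclose(maps.maps[0][support], 1.0)

    def test_rss_unity_on_support(self, default_coils, default_phantom):
        rss = default_coils.rss()
        assert np.abs(rss[default_phantom.support] - 1.0).max() < 1e-6
        assert np.all(rss[~default_phantom.support] == 0)

    def test_coils_are_distinct(self, default_coils, default_phantom):
        sup = default_phantom.support
        flat = [default_coils.maps[c][sup] for c in range(default_coils.n_coil)]
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                corr = abs(np.vdot(flat[i], flat[j])) / (
                    np.linalg.norm(flat[i]) * np.linalg.norm(flat[j])
                )
                assert corr < 0.999


class TestCoilEstimation:
    def test_recovers_truth_in_interior(self, small_phantom, small_coils):
        """Low-res estimate matches truth maps (modulo per-coil global
        phase) to <5% NRMSE in the support interior; the 1-2 voxel
        boundary shell is excluded since windowed low-resolution
        estimation cannot follow the support discontinuity."""
        from scipy import ndimage

        k, _ = wt.simulate_acquisition(small_phantom, small_coils, None, noise_sigma=0.0)
        est = wt.estimate_coil_maps_lowres(k, calib_size=16)
        interior = ndimage.binary_erosion(small_phantom.support, iterations=2)
        for c in range(small_coils.n_coil):
            t, e = small_coils.maps[c][interior], est.maps[c][interior]
            align = np.vdot(e, t)
            align /= abs(align)
            assert np.linalg.norm(t - align * e) / np.linalg.norm(t) < 0.05

    def test_single_uniform_coil(self):
        dims = (16, 16, 16)
        support = np.ones(dims, bool)
        coils = wt.make_coil_maps(1, dims, support)
        img = np.ones(dims, complex)
        op = wt.cartesian_operator(coils)
        k = op.forward(img)
        est = wt.estimate_coil_maps_lowres(k, calib_size=8)
        assert np.abs(np.abs(est.maps[0][est.support]) - 1.0).max() < 1e-6

    def test_rss_normalized(self, small_phantom, small_coils):
        k, _ = wt.simulate_acquisition(small_phantom, small_coils, None, noise_sigma=0.0)
        est = wt.estimate_coil_maps_lowres(k, calib_size=16)
        rss = est.rss()
        assert np.abs(rss[est.support] - 1.0).max() < 1e-9

    def test_small_calibration_rejected(self, small_phantom, small_coils):
        k, _ = wt.simulate_acquisition(small_phantom, small_coils, None, noise_sigma=0.0)
        with pytest.raises(ValueError, match="too small"):
            wt.estimate_coil_maps_lowres(k, calib_size=4)


class TestSimulation:
    def test_no_flow_equals_forward(self, small_phantom, small_coils):
        wave = wt.WaveParams(g_max=4.0, n_cyc=15, bw_per_pixel=121.0, n_read=32)
        k, op = wt.simulate_acquisition(small_phantom, small_coils, wave, noise_sigma=0.0)
        direct = op.forward(small_phantom.magnitude.astype(complex))
        assert np.allclose(k, direct)

    def test_flow_with_zero_velocity_identical(self, small_coils):
        spec = wt.PhantomSpec(dims=(32, 32, 16), flow_speed_mm_s=(0.0, 0.0))
        ph = wt.make_vessel_phantom(spec)
        wave = wt.WaveParams(g_max=4.0, n_cyc=15, bw_per_pixel=121.0, n_read=32)
        k_flow, _ = wt.simulate_acquisition(
            ph, small_coils, wave, noise_sigma=0.0, flow_on=True
        )
        k_static, _ = wt.simulate_acquisition(
            ph, small_coils, wave, noise_sigma=0.0, flow_on=False
        )
        assert np.allclose(k_flow, k_static, atol=1e-10)

    def test_two_voxel_toy_matches_signal_equation(self):
        """1 static + 1 flowing voxel against a hand-rolled per-sample
        DFT sum with the first-moment flow phase inserted."""
        dims = (16, 16, 16)
        fov = (200.0, 200.0, 26.4)
        spec = wt.PhantomSpec(dims=dims, fov_mm=fov, n_vessels=0)
        base = wt.make_vessel_phantom(spec)
        mag = np.zeros(dims)
        vel = np.zeros(dims + (3,))
        labels = np.zeros(dims, bool)
        mag[8, 8, 8] = 1.0  # static voxel
        mag[4, 10, 6] = 0.8  # flowing voxel
        labels[4, 10, 6] = True
        vel[4, 10, 6] = (0.0, 150.0, -60.0)
        ph = wt.DigitalPhantom(
            magnitude=mag, vessel_labels=labels, velocity=vel,
            support=np.ones(dims, bool), spec=spec,
        )
        coils = wt.make_coil_maps(1, dims, np.ones(dims, bool))
        wave = wt.WaveParams(g_max=1.0, n_cyc=3, bw_per_pixel=121.0, n_read=16, os_factor=2)
        k, op = wt.simulate_acquisition(ph, coils, wave, noise_sigma=0.0, flow_on=True)

        waveform = synthesize_waveforms(wave)
        traj = trajectory_from_waveform(waveform, wave, fov[0])
        moments = compute_moments(waveform)
        nxo, ny, nz = 32, 16, 16
        X = (np.arange(16) - 8) * fov[0] * 1e-3 / 16
        Y = (np.arange(16) - 8) * fov[1] * 1e-3 / 16
        Z = (np.arange(16) - 8) * fov[2] * 1e-3 / 16
        ky = (np.arange(16) - 8) / (fov[1] * 1e-3)
        kz = (np.arange(16) - 8) / (fov[2] * 1e-3)
        scale = 1.0 / np.sqrt(nxo * ny * nz)
        oracle = np.zeros((1, nxo, 16, 16), complex)
        for (ix, iy, iz), v in [((8, 8, 8), None), ((4, 10, 6), (0.0, 150.0, -60.0))]:
            amp = mag[ix, iy, iz]
            phase_x = (
                traj.kx * X[ix] + traj.ky_wave * Y[iy] + traj.kz_wave * Z[iz]
            )
            carrier = np.exp(-2j * np.pi * phase_x)
            if v is not None:
                carrier = carrier * np.exp(1j * flow_phase_series(moments, v))
            oracle[0] += (
                amp
                * scale
                * carrier[:, None, None]
                * np.exp(-2j * np.pi * np.add.outer(ky * Y[iy], kz * Z[iz]))[None]
            )
        assert np.abs(k - oracle).max() < 1e-10

    def test_noise_level_propagates(self, small_coils, small_phantom):
        """Background SD of a zero-signal simulation matches noise_sigma
        through the orthonormal pipeline within 5%."""
        spec = wt.PhantomSpec(dims=(32, 32, 16), n_vessels=0)
        zero = wt.DigitalPhantom(
            magnitude=np.zeros(spec.dims),
            vessel_labels=np.zeros(spec.dims, bool),
            velocity=np.zeros(spec.dims + (3,)),
            support=small_phantom.support,
            spec=spec,
        )
        sigma = 0.02
        k, op = wt.simulate_acquisition(zero, small_coils, None, noise_sigma=sigma, seed=5)
        img = op.adjoint(k)
        sup = small_phantom.support
        sd = np.sqrt(np.var(img.real[sup]) + np.var(img.imag[sup]))
        # adjoint with RSS=1 coils preserves the per-voxel complex noise SD
        assert sd == pytest.approx(sigma, rel=0.05)

    def test_full_pipeline_regression(self, small_phantom, small_coils):
        """Simulate -> least-squares recon at full sampling, noiseless:
        NRMSE < 0.5% inside support for wave and Cartesian modes."""
        for wave in (None, wt.WaveParams(g_max=4.0, n_cyc=15, bw_per_pixel=121.0, n_read=32)):
            k, op = wt.simulate_acquisition(small_phantom, small_coils, wave, noise_sigma=0.0)
            res = wt.recon_least_squares(k, op)
            assert nrmse(np.abs(res.image), small_phantom.magnitude, small_phantom.support) < 5e-3


class TestGhostRatio:
    def test_background_free_no_flow_is_noise_level(self, small_coils):
        spec = wt.PhantomSpec(
            dims=(32, 32, 16), background_intensity=1e-6, background_texture=0.0,
            flow_speed_mm_s=(0.0, 0.0),
        )
        ph = wt.make_vessel_phantom(spec)
        wave = wt.WaveParams(g_max=4.0, n_cyc=6, bw_per_pixel=121.0, n_read=32)
        k, op = wt.simulate_acquisition(ph, small_coils, wave, noise_sigma=0.0, flow_on=True)
        img = wt.recon_least_squares(k, op).image
        ratio = wt.ghost_to_signal_ratio(img, ph.vessel_labels, ph.support, 6)
        assert ratio < 0.01

    def test_empty_vessels_rejected(self):
        with pytest.raises(ValueError):
            wt.ghost_to_signal_ratio(
                np.ones((8, 8, 4)), np.zeros((8, 8, 4), bool), np.ones((8, 8, 4), bool), 2
            )
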