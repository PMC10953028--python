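"""g-factor, CBR, SSIM, vessel masking and MIP."""

import numpy as np
import pytest

import wavetof as wt
from wavetof.metrics import background_mask_from_vessels


class TestMip:
    def test_single_bright_voxel(self):
        v = np.zeros((8, 8, 4))
        v[2, 5, 1] = 7.0
        m = wt.mip(v, axis=2)
        assert m[2, 5] == 7.0 and (m > 0).sum() == 1

    def test_dominates_every_slice(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((16, 16, 8))
        m = wt.mip(v, axis=2)
        for z in range(8):
            assert np.all(m >= np.abs(v[:, :, z]))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((16, 16, 8)) + 1j * rng.standard_normal((16, 16, 8))
        m = wt.mip(v, axis=1)
        oracle = np.zeros((16, 8))
        for i in range(16):
            for k in range(8):
                oracle[i, k] = max(abs(v[i, j, k]) for j in range(16))
        assert np.allclose(m, oracle)


class TestCbr:
    def test_direct_formula(self):
        vol = np.zeros((10, 10, 2))
        vessel = np.zeros_like(vol, bool)
        bg = np.zeros_like(vol, bool)
        vessel[:5, 0, 0] = True
        bg[:, 5:, :] = True
        vol[vessel] = 10.0
        rng = np.random.default_rng(0)
        vol[bg] = np.abs(2.0 + 0.5 * rng.standard_normal(bg.sum()))
        sd = vol[bg].std()
        expected = (10.0 - vol[bg].mean()) / sd
        assert wt.cbr(vol, vessel, bg) == pytest.approx(expected)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(5.0, 1.0, (20, 20, 5))
        vessel = np.zeros_like(vol, bool)
        bg = np.zeros_like(vol, bool)
        vessel[:10] = True
        bg[10:] = True
        assert abs(wt.cbr(vol, vessel, bg)) < 3.0 / np.sqrt(bg.sum())

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(0, 1, (10, 10, 4))
        vessel = vol > 0.8
        bg = vol < 0.5
        assert wt.cbr(vol + 5.0, vessel, bg) == pytest.approx(wt.cbr(vol, vessel, bg))

    def test_overlapping_masks_rejected(self):
        vol = np.ones((4, 4, 2))
        m = np.ones_like(vol, bool)
        with pytest.raises(ValueError):
            wt.cbr(vol, m, m)


@pytest.fixture(scope="module")
def mips(default_phantom):
    ref = wt.mip(default_phantom.magnitude)
    rng = np.random.default_rng(0)
    noisy = ref + 0.05 * rng.standard_normal(ref.shape)
    return ref, np.abs(noisy)


class TestSsim:
    def test_identical_images_unity(self, mips):
        assert wt.ssim(mips[0], mips[0]) == pytest.approx(1.0)

    def test_symmetry(self, mips):
        a, b = mips
        assert wt.ssim(a, b) == pytest.approx(wt.ssim(b, a), abs=1e-12)

    def test_contrast_inversion_scores_low(self, mips):
        a = mips[0]
        assert wt.ssim(a, a.max() - a) < 0.5

    def test_matches_reference_implementation(self, mips):
        from skimage.metrics import structural_similarity

        a, b = mips
        dr = max(a.max(), b.max())
        ref = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
            data_range=dr,
        )
        assert wt.ssim(a, b, data_range=dr) == pytest.approx(ref, abs=1e-12)

    def test_vessel_masked_full_mask_equals_standard(self, mips):
        a, b = mips
        full = np.ones(a.shape, bool)
        assert wt.vessel_masked_ssim(a, b, full) == pytest.approx(
            wt.ssim(a, b), abs=1e-12
        )

    def test_background_corruption_spares_vessel_score(self, default_phantom):
        """Corrupting only background pixels leaves the vessel-masked
        score above the standard score."""
        ref = wt.mip(default_phantom.magnitude)
        vmask = wt.mip(default_phantom.vessel_labels.astype(float)) > 0
        rng = np.random.default_rng(1)
        corrupted = ref.copy()
        bg = ~vmask
        corrupted[bg] += 0.3 * rng.standard_normal(bg.sum())
        corrupted = np.abs(corrupted)
        dr = float(ref.max())
        assert wt.vessel_masked_ssim(corrupted, ref, vmask, data_range=dr) >= wt.ssim(
            corrupted, ref, data_range=dr
        )

    def test_empty_mask_rejected(self, mips):
        with pytest.raises(ValueError):
            wt.vessel_masked_ssim(mips[0], mips[1], np.zeros(mips[0].shape, bool))


class TestVesselMask:
    def test_dice_against_phantom_truth(self):
        """Segmentation recovers supra-voxel vessels (Dice >= 0.9) and
        labels no background.  Vessels thick enough to stay resolved
        after the distal taper are used: sub-voxel partial-volume tips
        legitimately fall below any intensity threshold."""
        ph = wt.make_vessel_phantom(
            wt.PhantomSpec(vessel_radius_mm=(4.0, 7.0), n_vessels=4, seed=2)
        )
        ref = wt.mip(ph.magnitude)
        truth = wt.mip(ph.vessel_labels.astype(float)) > 0
        mask = wt.make_vessel_mask(ref)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            wt.make_vessel_mask(np.ones((32, 32)))

    def test_scale_invariance(self, default_phantom):
        ref = wt.mip(default_phantom.magnitude)
        assert np.array_equal(wt.make_vessel_mask(ref), wt.make_vessel_mask(10.0 * ref))

    def test_background_mask_disjoint_from_vessels(self, default_phantom):
        ref = wt.mip(default_phantom.magnitude)
        vm = wt.make_vessel_mask(ref)
        support = wt.mip(default_phantom.support.astype(float)) > 0
        bg = background_mask_from_vessels(support, vm)
        assert not np.any(bg & vm)
        assert bg.any()


class TestGFactor:
    def test_unaccelerated_g_is_unity(self):
        """R=1, single uniform coil: g within 0.1 of 1 at 100 replicas."""
        dims = (16, 16, 16)
        support = np.ones(dims, bool)
        coils = wt.make_coil_maps(1, dims, support)
        op = wt.cartesian_operator(coils, wt.full_mask(16, 16))
        recon_fn = lambda k, o: o.adjoint(k)
        g = wt.gfactor_pseudo_replica(op, recon_fn, n_replicas=100, seed=0)
        assert abs(g.g_mean - 1.0) < 0.1
        assert np.all(g.g[g.valid] >= 0)

    def test_two_coil_sense_matches_closed_form(self):
        """1D R=2 SENSE: Monte-Carlo g matches the analytic
        sqrt([(S^H S)^-1]_rr (S^H S)_rr) within 5% at 500 replicas."""
        ny = 16
        dims = (1, ny, 1)
        y = np.linspace(-1, 1, ny)
        maps = np.zeros((2, 1, ny, 1), complex)
        maps[0, 0, :, 0] = np.exp(-((y - 0.6) ** 2))
        maps[1, 0, :, 0] = np.exp(-((y + 0.6) ** 2)) * np.exp(1j * 0.7 * y)
        rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        maps /= rss
        coils = wt.CoilMaps(maps=maps, support=np.ones(dims, bool))
        grid = np.zeros((ny, 1), bool)
        grid[::2] = True
        mask = wt.SamplingMask(grid=grid, R_nominal=2.0, kind="caipi")
        op = wt.cartesian_operator(coils, mask)
        params = wt.ReconParams(ls_tol=1e-10, ls_maxiter=300)
        recon_fn = lambda k, o: wt.recon_least_squares(k, o, params).image
        g = wt.gfactor_pseudo_replica(op, recon_fn, n_replicas=500, seed=4)
        # analytic SENSE g-factor per aliased pair
        S = coils.maps[:, 0, :, 0]  # (2, ny)
        g_true = np.zeros(ny)
        for i in range(ny // 2):
            Sp = S[:, [i, i + ny // 2]]
            StS = Sp.conj().T @ Sp
            inv = np.linalg.inv(StS)
            for a, j in enumerate((i, i + ny // 2)):
                g_true[j] = np.sqrt((inv[a, a] * StS[a, a]).real)
        mc = g.g[0, :, 0]
        assert np.abs(mc - g_true).max() / g_true.max() < 0.05

    def test_sd_full_zero_marked_invalid(self):
        dims = (16, 16, 16)
        support = np.zeros(dims, bool)
        support[4:12, 4:12, 4:12] = True
        coils = wt.make_coil_maps(2, dims, support, seed=0)
        op = wt.cartesian_operator(coils, wt.full_mask(16, 16))
        recon_fn = lambda k, o: o.adjoint(k)
        g = wt.gfactor_pseudo_replica(op, recon_fn, n_replicas=20, seed=0)
        assert not g.valid[0, 0, 0]  # outside support the maps are zero
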