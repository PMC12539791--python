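import numpy as np
import pytest

from dabsms import losses
from dabsms.losses import (
    DistanceMap,
    LossWeights,
    MSStats,
    WeightMap,
    loss_cc,
    loss_cc_grad,
    loss_grad,
    loss_grad_grad,
    loss_ms,
    loss_ms_grad,
    loss_wgrad,
    loss_wgrad_grad,
    ms_stats,
    signed_distance,
    total_loss,
    weight_map,
)
from dabsms.volumes import AtlasBundle, CubeGrid, ImageVolume, MaskVolume
from dabsms.warp import DisplacementField

from oracles import (
    oracle_loss_cc,
    oracle_loss_grad,
    oracle_loss_wgrad,
    oracle_ms_stats,
    oracle_nearest_opposite_distance,
)


@pytest.fixture()
def field8(rng, grid8):
    return DisplacementField(u=rng.standard_normal((3, 8, 8, 8)), grid=grid8)


class TestLossCC:
    def test_identical_images_zero(self, random_volume8):
        assert loss_cc(random_volume8, random_volume8) == pytest.approx(0.0, abs=1e-12)

    def test_linear_relation_zero(self, random_volume8):
        scaled = random_volume8.with_voxels(2.0 * random_volume8.voxels + 3.0)
        assert loss_cc(scaled, random_volume8) == pytest.approx(0.0, abs=1e-12)

    def test_negated_image_one(self, random_volume8):
        neg = random_volume8.with_voxels(-random_volume8.voxels)
        assert loss_cc(neg, random_volume8) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_errors(self, random_volume8):
        const = random_volume8.with_voxels(np.full((8, 8, 8), 3.0))
        with pytest.raises(ValueError):
            loss_cc(const, random_volume8)

    def test_range_and_negation_antisymmetry(self, rng, random_volume8):
        other = ImageVolume(voxels=rng.standard_normal((8, 8, 8)))
        v = loss_cc(other, random_volume8)
        assert 0.0 <= v <= 1.0
        neg = other.with_voxels(-other.voxels)
        assert loss_cc(neg, random_volume8) == pytest.approx(1.0 - v, abs=1e-12)

    def test_matches_oracle(self, rng, random_volume8):
        other = ImageVolume(voxels=rng.standard_normal((8, 8, 8)))
        expected = oracle_loss_cc(other.voxels, random_volume8.voxels)
        assert loss_cc(other, random_volume8) == pytest.approx(expected, rel=1e-9)


class TestSignedDistance:
    def test_slab_face_distance(self):
        m = np.zeros((10, 10, 10), np.uint8)
        m[:4] = 1  # flat slab
        for s in (1.0, 0.5):
            d = signed_distance(MaskVolume(voxels=m, spacing=(s, s, s)))
            assert d.values[6, 5, 5] == pytest.approx(3 * s)  # 3 voxels beyond the face at index 3
            assert d.values[5, 5, 5] == pytest.approx(2 * s)

    def test_interior_negative(self, blob_mask8):
        d = signed_distance(blob_mask8)
        assert (d.values[blob_mask8.voxels.astype(bool)] < 0).all()
        assert (d.values[~blob_mask8.voxels.astype(bool)] > 0).all()

    def test_complement_flips_sign(self, blob_mask8):
        d = signed_distance(blob_mask8)
        comp = MaskVolume(voxels=1 - blob_mask8.voxels, spacing=blob_mask8.spacing)
        dc = signed_distance(comp)
        assert np.all(np.sign(dc.values) == -np.sign(d.values))

    def test_matches_exhaustive_search_on_small_mask(self):
        m = np.zeros((5, 5, 5), np.uint8)
        m[1:3, 1:4, 2] = 1
        sp = (1.0, 1.0, 2.0)
        d = signed_distance(MaskVolume(voxels=m, spacing=sp))
        for idx in [(0, 0, 0), (2, 2, 2), (4, 4, 4), (1, 2, 2), (3, 3, 1)]:
            assert d.values[idx] == pytest.approx(oracle_nearest_opposite_distance(m, sp, *idx))

    def test_degenerate_masks_error(self):
        with pytest.raises(ValueError):
            signed_distance(MaskVolume(voxels=np.zeros((4, 4, 4), np.uint8)))
        with pytest.raises(ValueError):
            signed_distance(MaskVolume(voxels=np.ones((4, 4, 4), np.uint8)))


class TestWeightMap:
    def test_closed_form_values(self):
        d = DistanceMap(values=np.array([[[0.0, 2.5], [4.0, 7.0]], [[-2.5, 1.0], [-1.0, 0.5]]]), spacing=(1, 1, 1))
        w = weight_map(d, 1.0, 4.0)
        assert w.values[0, 0, 0] == pytest.approx(1.0)
        assert w.values[0, 0, 1] == pytest.approx(0.75)
        assert w.values[0, 1, 0] == pytest.approx(0.5)
        assert w.values[0, 1, 1] == pytest.approx(0.5)
        assert w.values[1, 0, 0] == pytest.approx(0.75)  # |D| used
        assert w.values[1, 0, 1] == pytest.approx(1.0)  # below tL clamps to tL
        assert w.values[1, 1, 1] == pytest.approx(1.0)

    def test_range_invariant_on_random_mask(self, rng):
        m = (rng.random((12, 12, 12)) > 0.6).astype(np.uint8)
        m[0, 0, 0], m[1, 1, 1] = 0, 1  # ensure both classes
        w = weight_map(signed_distance(MaskVolume(voxels=m)), 1.0, 4.0)
        assert w.values.min() >= 0.5
        assert w.values.max() <= 1.0

    def test_invalid_thresholds(self):
        d = DistanceMap(values=np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            weight_map(d, 4.0, 1.0)


class TestLossGrad:
    def test_constant_field_zero(self, grid8):
        f = DisplacementField(u=np.full((3, 8, 8, 8), 2.5), grid=grid8)
        assert loss_grad(f) == pytest.approx(0.0)

    def test_unit_ramp_matches_oracle(self, grid8):
        u = np.zeros((3, 8, 8, 8))
        u[0] = np.broadcast_to(np.arange(8.0)[:, None, None], (8, 8, 8))
        f = DisplacementField(u=u, grid=grid8)
        assert loss_grad(f) == pytest.approx(oracle_loss_grad(u), rel=1e-12)

    def test_equals_wgrad_with_unit_weights(self, field8):
        w = WeightMap(values=np.ones((8, 8, 8)))
        assert loss_wgrad(field8, w) == pytest.approx(loss_grad(field8), rel=1e-12)


class TestLossWGrad:
    def test_constant_field_zero_any_weights(self, rng, grid8):
        f = DisplacementField(u=np.full((3, 8, 8, 8), -1.0), grid=grid8)
        w = WeightMap(values=rng.uniform(0.5, 1.0, (8, 8, 8)))
        assert loss_wgrad(f, w) == pytest.approx(0.0)

    def test_uniform_half_weight_quarter_of_grad(self, field8):
        w = WeightMap(values=np.full((8, 8, 8), 0.5))
        assert loss_wgrad(field8, w) == pytest.approx(0.25 * loss_grad(field8), rel=1e-12)

    def test_bounds_relative_to_grad(self, rng, field8):
        w = WeightMap(values=rng.uniform(0.5, 1.0, (8, 8, 8)))
        lw = loss_wgrad(field8, w)
        lg = loss_grad(field8)
        assert 0.25 * lg - 1e-12 <= lw <= lg + 1e-12

    def test_grid_mismatch_errors(self, field8):
        with pytest.raises(ValueError):
            loss_wgrad(field8, WeightMap(values=np.ones((4, 4, 4))))


class TestMSStats:
    def test_two_level_image(self, blob_mask8):
        img = np.where(blob_mask8.voxels > 0, 5.0, 2.0)
        s = ms_stats(ImageVolume(voxels=img), blob_mask8)
        assert (s.mu_int, s.mu_ext) == (5.0, 2.0)
        assert (s.var_int, s.var_ext) == (0.0, 0.0)
        assert loss_ms(s) == 0.0

    def test_uniform_image(self, blob_mask8):
        s = ms_stats(ImageVolume(voxels=np.full((8, 8, 8), 3.0)), blob_mask8)
        assert s.mu_int == s.mu_ext == 3.0
        assert loss_ms(s) == 0.0

    def test_hand_computed_example(self):
        # foreground {1, 3}, background {0, 0, 6} -> mu 2/2, var 1/8, loss 9
        img = np.array([1.0, 3.0, 0.0, 0.0, 6.0]).reshape(5, 1, 1)
        mask = MaskVolume(voxels=np.array([1, 1, 0, 0, 0]).reshape(5, 1, 1))
        s = ms_stats(img, mask)
        assert s.mu_int == pytest.approx(2.0)
        assert s.var_int == pytest.approx(1.0)
        assert s.mu_ext == pytest.approx(2.0)
        assert s.var_ext == pytest.approx(8.0)
        assert loss_ms(s) == pytest.approx(9.0)

    def test_population_variance_convention(self, rng, blob_mask8):
        img = rng.standard_normal((8, 8, 8))
        s = ms_stats(ImageVolume(voxels=img), blob_mask8)
        fg = img[blob_mask8.voxels.astype(bool)]
        assert s.var_int == pytest.approx(np.var(fg), rel=1e-12)  # divide-by-count

    def test_shift_invariance_of_loss(self, rng, blob_mask8):
        img = rng.standard_normal((8, 8, 8))
        s0 = ms_stats(ImageVolume(voxels=img), blob_mask8)
        s1 = ms_stats(ImageVolume(voxels=img + 17.0), blob_mask8)
        assert loss_ms(s1) == pytest.approx(loss_ms(s0), rel=1e-9)

    def test_degenerate_mask_errors(self, random_volume8):
        with pytest.raises(ValueError):
            ms_stats(random_volume8, MaskVolume(voxels=np.zeros((8, 8, 8), np.uint8)))
        with pytest.raises(ValueError):
            ms_stats(random_volume8, MaskVolume(voxels=np.ones((8, 8, 8), np.uint8)))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            MSStats(mu_int=0, mu_ext=0, var_int=-1.0, var_ext=0)


class TestOracleEquivalence:
    """Each loss term against its independent triple-loop implementation."""

    N_TRIALS = 20

    def test_all_terms_on_random_inputs(self, grid8):
        rng = np.random.default_rng(99)
        for _ in range(self.N_TRIALS):
            warped = rng.standard_normal((8, 8, 8))
            atlas = rng.standard_normal((8, 8, 8))
            u = rng.standard_normal((3, 8, 8, 8))
            w_map = rng.uniform(0.5, 1.0, (8, 8, 8))
            mask = (rng.random((8, 8, 8)) > 0.5).astype(np.uint8)
            mask[0, 0, 0], mask[1, 1, 1] = 0, 1
            f = DisplacementField(u=u, grid=grid8)

            assert loss_cc(ImageVolume(voxels=warped), ImageVolume(voxels=atlas)) == pytest.approx(
                oracle_loss_cc(warped, atlas), rel=1e-9
            )
            assert loss_grad(f) == pytest.approx(oracle_loss_grad(u), rel=1e-9)
            assert loss_wgrad(f, WeightMap(values=w_map)) == pytest.approx(
                oracle_loss_wgrad(u, w_map), rel=1e-9
            )
            s = ms_stats(ImageVolume(voxels=warped), MaskVolume(voxels=mask))
            mu_i, mu_e, var_i, var_e = oracle_ms_stats(warped, mask)
            assert s.mu_int == pytest.approx(mu_i, rel=1e-9)
            assert s.mu_ext == pytest.approx(mu_e, rel=1e-9)
            assert s.var_int == pytest.approx(var_i, rel=1e-9)
            assert s.var_ext == pytest.approx(var_e, rel=1e-9)
            assert loss_ms(s) == pytest.approx(var_i + var_e, rel=1e-9)


class TestTotalLoss:
    def test_preset_arithmetic(self, bundle8, field8, monkeypatch):
        monkeypatch.setattr(losses, "loss_cc", lambda *a: 0.2)
        monkeypatch.setattr(losses, "loss_grad", lambda *a: 0.1)
        monkeypatch.setattr(losses, "ms_stats", lambda *a: MSStats(0, 0, 0.3, 0.0))
        total, comps = total_loss(bundle8.image, bundle8, field8, "iac")
        assert total == pytest.approx(0.2 + 0.5 * 0.1 + 0.5 * 0.3)
        assert comps == {"cc": 0.2, "grad": 0.1, "ms": 0.3}

    def test_single_term(self, bundle8, field8, rng):
        w = LossWeights(w_cc=0.0, w_grad=2.0)
        warped = ImageVolume(voxels=rng.standard_normal((8, 8, 8)))
        total, comps = total_loss(warped, bundle8, field8, w)
        assert total == pytest.approx(2.0 * comps["grad"])
        assert set(comps) == {"grad"}

    def test_vxm_preset_skips_ms(self, bundle8, field8, rng, monkeypatch):
        calls = []
        monkeypatch.setattr(losses, "ms_stats", lambda *a: calls.append(1))
        warped = ImageVolume(voxels=rng.standard_normal((8, 8, 8)))
        total_loss(warped, bundle8, field8, "vxm")
        assert calls == []

    def test_preset_table(self):
        assert losses.PRESETS["vxm"] == LossWeights(1.0, 0.5, 0.0, 0.0)
        assert losses.PRESETS["iac"] == LossWeights(1.0, 0.5, 0.0, 0.5)
        assert losses.PRESETS["segthor"] == LossWeights(1.0, 1.0, 0.0, 0.5)
        assert losses.PRESETS["hkits21"] == LossWeights(1.0, 0.0, 2.0, 0.5)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            LossWeights(w_cc=-1.0)


class TestGradients:
    """Analytic gradients against central finite differences (1e-4 relative)."""

    def _fd_check(self, f, x, analytic, n=12, eps=1e-6, seed=5):
        rs = np.random.default_rng(seed)
        for _ in range(n):
            idx = tuple(rs.integers(s) for s in x.shape)
            xp = x.copy()
            xm = x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (f(xp) - f(xm)) / (2 * eps)
            assert analytic[idx] == pytest.approx(num, rel=1e-4, abs=1e-10)

    def test_cc_gradient(self, rng, random_volume8):
        w = rng.standard_normal((8, 8, 8))
        g = loss_cc_grad(ImageVolume(voxels=w), random_volume8)
        self._fd_check(lambda x: loss_cc(ImageVolume(voxels=x), random_volume8), w, g)

    def test_ms_gradient(self, rng, blob_mask8):
        w = rng.standard_normal((8, 8, 8))
        g = loss_ms_grad(ImageVolume(voxels=w), blob_mask8)
        self._fd_check(lambda x: loss_ms(ms_stats(ImageVolume(voxels=x), blob_mask8)), w, g)

    def test_grad_gradient(self, rng, grid8):
        u = rng.standard_normal((3, 8, 8, 8))
        g = loss_grad_grad(DisplacementField(u=u, grid=grid8))
        self._fd_check(lambda x: loss_grad(DisplacementField(u=x, grid=grid8)), u, g)

    def test_wgrad_gradient(self, rng, grid8):
        u = rng.standard_normal((3, 8, 8, 8))
        w = WeightMap(values=rng.uniform(0.5, 1.0, (8, 8, 8)))
        g = loss_wgrad_grad(DisplacementField(u=u, grid=grid8), w)
        self._fd_check(lambda x: loss_wgrad(DisplacementField(u=x, grid=grid8), w), u, g)

    def test_full_chain_through_warp(self, rng, bundle8, grid8):
        from dabsms.warp import _identity_coords, trilinear_sample, trilinear_sample_with_grad

        target = rng.standard_normal((8, 8, 8))
        u = rng.uniform(-0.4, 0.4, (3, 8, 8, 8))
        weights = LossWeights(w_cc=1.0, w_grad=0.5, w_wgrad=0.5, w_ms=0.5)
        bundle8.ensure_weight_map()

        def total_of(uu):
            fld = DisplacementField(u=uu, grid=grid8)
            warped = trilinear_sample(target, _identity_coords((8, 8, 8)) + uu)
            return losses.total_loss(warped, bundle8, fld, weights)[0]

        fld = DisplacementField(u=u, grid=grid8)
        warped, spatial = trilinear_sample_with_grad(target, _identity_coords((8, 8, 8)) + u)
        _, _, d_warped, d_u = losses.total_loss_grad(warped, bundle8, fld, weights)
        analytic = d_u + spatial * d_warped[None]
        self._fd_check(total_of, u, analytic, n=15)
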