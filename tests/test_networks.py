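"""Architecture contracts, loss analytics, and backprop correctness."""

import numpy as np
import pytest

from hccseg.networks import (CompositeLossBreakdown, DcnnConfig, FusionConfig,
                             binarize, build_dcnn, build_dfn, composite_loss,
                             dice_loss, dice_loss_grad, load_weights,
                             save_weights)
from hccseg.nn import AuxEncoderHead, DcnnNet, FusionNet


class TestDcnnArchitecture:
    @pytest.mark.parametrize("size", [16, 32, 64])
    def test_output_matches_input_shape_and_is_probability(self, size, rng):
        net = DcnnNet(base_channels=2, seed=0)
        x = rng.random((2, 1, size, size), dtype=np.float32)
        out = net.forward(x, train=False)
        assert out.shape == (2, 1, size, size)
        assert out.min() >= 0.0 and out.max() <= 1.0

    @pytest.mark.parametrize("size", [100, 12, 7])
    def test_rejects_sizes_not_divisible_by_eight(self, size, rng):
        net = DcnnNet(base_channels=2, seed=0)
        with pytest.raises(ValueError, match="divisible by 8"):
            net.forward(rng.random((1, 1, size, size), dtype=np.float32))
        with pytest.raises(ValueError):
            DcnnConfig(input_size=(size, size))

    def test_seeded_init_is_reproducible(self):
        a = build_dcnn(DcnnConfig(input_size=(16, 16), base_channels=2), seed=9)
        b = build_dcnn(DcnnConfig(input_size=(16, 16), base_channels=2), seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_weight_serialization_roundtrip_preserves_forward(self, tmp_path, rng):
        net = DcnnNet(base_channels=2, seed=3)
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        net.forward(x, train=True)  # move BN running stats off their init
        ref = net.forward(x, train=False)
        save_weights(net, tmp_path / "w.npz", meta={"seed": 3})
        other = DcnnNet(base_channels=2, seed=99)
        load_weights(other, tmp_path / "w.npz")
        np.testing.assert_array_equal(other.forward(x, train=False), ref)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        t = (rng.random((8, 8)) > 0.6).astype(float)
        assert dice_loss(t, t, smooth=0.0) == pytest.approx(0.0)

    def test_disjoint_masks_lose_everything(self):
        a = np.zeros((4, 4)); a[:2] = 1
        b = np.zeros((4, 4)); b[2:] = 1
        assert dice_loss(a, b, smooth=0.0) == pytest.approx(1.0)

    def test_uniform_half_prediction_on_half_target(self):
        # hand evaluation: pred=0.5 everywhere, target covers half the grid:
        # 1 - 2*(0.5*2)/(0.5*4 + 2) = 1 - 2/4 = 0.5
        target = np.array([[1.0, 1.0], [0.0, 0.0]])
        pred = np.full((2, 2), 0.5)
        assert dice_loss(pred, target, smooth=0.0) == pytest.approx(0.5)

    def test_symmetric_in_binary_arguments(self, rng):
        a = (rng.random((6, 6)) > 0.5).astype(float)
        b = (rng.random((6, 6)) > 0.5).astype(float)
        assert dice_loss(a, b, 1.0) == pytest.approx(dice_loss(b, a, 1.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.random((5, 5))
        t = (rng.random((5, 5)) > 0.5).astype(float)
        _, g = dice_loss_grad(p, t, smooth=1.0)
        eps = 1e-7
        for idx in [(0, 0), (2, 3), (4, 4)]:
            pp = p.copy(); pp[idx] += eps
            pm = p.copy(); pm[idx] -= eps
            num = (dice_loss(pp, t) - dice_loss(pm, t)) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6)


class TestCompositeLoss:
    def test_weighted_sum_identity(self):
        # alpha-weighted sub-losses plus the fusion loss, exactly
        g = np.zeros((2, 2)); g[0, 0] = 1
        sub1 = g.astype(float); sub2 = g.astype(float); fused = g.astype(float)
        bd = composite_loss(g, (sub1, sub2), fused, alphas=(0.5, 0.5), smooth=0.0)
        assert bd.total == pytest.approx(0.0)

    def test_linearity_in_alphas(self, rng):
        g = (rng.random((4, 4)) > 0.5).astype(float)
        s1, s2, f = rng.random((3, 4, 4))
        for a1, a2 in [(0.0, 0.0), (0.5, 0.5), (2.0, 0.3)]:
            bd = composite_loss(g, (s1, s2), f, alphas=(a1, a2))
            expected = a1 * bd.subnet_losses[0] + a2 * bd.subnet_losses[1] + bd.fusion_loss
            assert bd.total == pytest.approx(expected, abs=1e-12)

    def test_zero_alphas_leave_fusion_loss_alone(self, rng):
        g = (rng.random((4, 4)) > 0.5).astype(float)
        s1, s2, f = rng.random((3, 4, 4))
        bd = composite_loss(g, (s1, s2), f, alphas=(0.0, 0.0))
        assert bd.total == pytest.approx(bd.fusion_loss)

    def test_negative_alpha_rejected(self, rng):
        g = np.zeros((2, 2))
        with pytest.raises(ValueError):
            composite_loss(g, (g, g), g, alphas=(-0.1, 0.5))


class TestBinarize:
    def test_below_threshold_empty(self):
        assert binarize(np.full((3, 3), 0.4), 0.5).sum() == 0

    def test_tie_goes_to_foreground(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).sum() == 9

    def test_counts_match_brute_force(self, rng):
        s = rng.random((16, 16))
        out = binarize(s, 0.3)
        brute = sum(1 for v in s.ravel() if v >= 0.3)
        assert int(out.sum()) == brute

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), 1.0)


class TestFusionNetwork:
    def test_forward_contract_and_submap_compositionality(self, rng):
        cfg = FusionConfig(fusion_channels=2)
        fnet = build_dfn(cfg, DcnnConfig(input_size=(16, 16), base_channels=2), seed=1)
        x1 = rng.random((2, 1, 16, 16), dtype=np.float32)
        x2 = rng.random((2, 1, 16, 16), dtype=np.float32)
        o1, o2, p = fnet.forward(x1, x2, train=False)
        assert p.shape == x1.shape
        assert p.min() >= 0 and p.max() <= 1
        # sub-maps equal running each sub-network standalone on its phase
        np.testing.assert_array_equal(o1, fnet.subnets[0].forward(x1, train=False))
        np.testing.assert_array_equal(o2, fnet.subnets[1].forward(x2, train=False))

    def test_mismatched_phase_shapes_rejected(self, rng):
        fnet = FusionNet(base_channels=2, fusion_channels=2, seed=0)
        with pytest.raises(ValueError):
            fnet.forward(rng.random((1, 1, 16, 16), dtype=np.float32),
                         rng.random((1, 1, 24, 24), dtype=np.float32))

    def test_full_network_gradient_matches_finite_differences(self, rng):
        # one scalar check per parameter group, in float64 for accuracy
        fnet = FusionNet(base_channels=2, fusion_channels=2, seed=0, dtype=np.float64)
        x1 = rng.random((1, 1, 16, 16))
        x2 = rng.random((1, 1, 16, 16))
        gt = (rng.random((1, 1, 16, 16)) > 0.8).astype(float)

        def total_loss():
            o1, o2, p = fnet.forward(x1, x2, train=True)
            from hccseg.networks import composite_loss
            return composite_loss(gt, (o1, o2), p, (0.5, 0.5)).total

        o1, o2, p = fnet.forward(x1, x2, train=True)
        for prm in fnet.params():
            prm.zero_grad()
        fnet.composite_backward(gt, o1, o2, p, (0.5, 0.5))
        params = fnet.params()
        check = [params[0], params[40], params[-1], params[-4]]
        eps = 1e-6
        for prm in check:
            idx = tuple(np.unravel_index(0, prm.value.shape))
            orig = prm.value[idx]
            prm.value[idx] = orig + eps
            lp = total_loss()
            prm.value[idx] = orig - eps
            lm = total_loss()
            prm.value[idx] = orig
            assert prm.grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    def test_fusion_config_validation(self):
        with pytest.raises(ValueError):
            FusionConfig(alphas=(-1.0, 0.5))
        with pytest.raises(ValueError):
            FusionConfig(fusion_mode="max")


class TestAuxHead:
    def test_restores_input_resolution(self, rng):
        net = DcnnNet(base_channels=2, seed=0)
        aux = AuxEncoderHead(16, seed=0)
        x = rng.random((1, 1, 24, 24), dtype=np.float32)
        b = net.forward_encoder(x, train=False)
        out = aux.forward(b, train=False)
        assert out.shape == (1, 1, 24, 24)
        assert out.min() >= 0 and out.max() <= 1
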