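"""Semantic-texture fusion: alignment, attention, CoupleConv oracles."""

import numpy as np
import pytest

from sgnet import nn
from sgnet.nn import Tensor, conv2d
from sgnet.stfu import STFU, CoupleConv, TripletAttention


class TestAlign:
    def test_outputs_at_deep_resolution(self, rng):
        nn.init.seed_all(0)
        stfu = STFU()
        shallow = Tensor(rng.standard_normal((1, 96, 64, 64)).astype(np.float32))
        deep = Tensor(rng.standard_normal((1, 96, 32, 32)).astype(np.float32))
        x_i, x_ip1 = stfu.align(shallow, deep)
        assert x_i.shape == (1, 96, 32, 32)
        assert x_ip1.shape == (1, 96, 32, 32)

    def test_equal_shapes_rejected(self, rng):
        nn.init.seed_all(0)
        stfu = STFU()
        x = Tensor(rng.standard_normal((1, 96, 32, 32)).astype(np.float32))
        with pytest.raises(ValueError, match="twice"):
            stfu.align(x, x)

    def test_constant_input_stays_constant_after_pooling(self):
        x = Tensor(np.full((1, 4, 8, 8), 3.5))
        pooled = nn.avg_pool2d(x, 2)
        assert np.allclose(pooled.data, 3.5)


class TestTripletAttention:
    def test_shape_preserved(self, rng):
        nn.init.seed_all(1)
        att = TripletAttention()
        x = Tensor(rng.standard_normal((2, 96, 16, 16)).astype(np.float32))
        assert att(x).shape == (2, 96, 16, 16)

    def test_gates_bounded_by_sigmoid(self, rng):
        nn.init.seed_all(1)
        att = TripletAttention()
        x = Tensor(rng.standard_normal((1, 8, 6, 6)) * 10)
        y = att(x).data
        # each branch output is x * gate with gate in (0,1): |y| <= |x|
        assert (np.abs(y) <= np.abs(x.data) + 1e-12).all()

    def test_branches_agree_on_symmetric_constant_input(self):
        """With shared gate weights and a C=H=W constant cube, all three
        branches compute the same gate pattern, each in its rotated frame:
        undoing the rotation recovers the plain spatial branch exactly."""
        nn.init.seed_all(2)
        att = TripletAttention()
        for conv in (att.conv_ch, att.conv_hw):
            conv.weight.data = att.conv_cw.weight.data.copy()
            conv.bias.data = att.conv_cw.bias.data.copy()
        x = Tensor(np.full((1, 12, 12, 12), 0.7, dtype=np.float32))
        b1 = att._gate(x.transpose(0, 2, 1, 3), att.conv_ch).transpose(0, 2, 1, 3)
        b2 = att._gate(x.transpose(0, 3, 2, 1), att.conv_cw).transpose(0, 3, 2, 1)
        b3 = att._gate(x, att.conv_hw)
        assert np.allclose(b1.transpose(0, 2, 1, 3).data, b3.data, atol=1e-7)
        assert np.allclose(b2.transpose(0, 3, 2, 1).data, b3.data, atol=1e-7)


class TestCoupleConv:
    def test_matches_explicit_branch_sum_oracle(self, rng):
        """CoupleConv equals a hand-rolled loop over branch convolutions."""
        nn.init.seed_all(3)
        cc = CoupleConv(channels=8, kernels=(1, 3, 5), groups=4)
        cc.alpha_logits.data = rng.standard_normal(3).astype(np.float32)
        x = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        out = cc(x).data
        logits = cc.alpha_logits.data
        alpha = np.exp(logits - logits.max())
        alpha = alpha / alpha.sum()
        oracle = np.zeros_like(out)
        for i, k in enumerate((1, 3, 5)):
            br = getattr(cc, f"branch{i}")
            oracle += alpha[i] * conv2d(x, br.weight, br.bias,
                                        padding=k // 2, groups=4).data
        assert np.abs(out - oracle).max() < 1e-6

    def test_equal_logits_give_uniform_weights(self):
        nn.init.seed_all(3)
        cc = CoupleConv(channels=8, kernels=(1, 3, 5), groups=4)
        assert np.allclose(cc.branch_weights().data, 1 / 3, atol=1e-7)

    def test_zeroed_tail_branches_leave_single_branch(self, rng):
        nn.init.seed_all(4)
        cc = CoupleConv(channels=8, kernels=(1, 3, 5), groups=4)
        for i in (1, 2):
            br = getattr(cc, f"branch{i}")
            br.weight.data[:] = 0
            br.bias.data[:] = 0
        x = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        b0 = getattr(cc, "branch0")
        expected = cc.branch_weights().data[0] * conv2d(
            x, b0.weight, b0.bias, padding=0, groups=4).data
        assert np.allclose(cc(x).data, expected, atol=1e-7)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            CoupleConv(channels=10, kernels=(1, 3), groups=4)


class TestSTFUForward:
    @pytest.mark.parametrize("hs,hd", [(64, 32), (16, 8)])
    def test_output_at_deep_resolution(self, hs, hd, rng):
        nn.init.seed_all(5)
        stfu = STFU()
        shallow = Tensor(rng.standard_normal((1, 96, hs, hs)).astype(np.float32))
        deep = Tensor(rng.standard_normal((1, 96, hd, hd)).astype(np.float32))
        assert stfu(shallow, deep).shape == (1, 96, hd, hd)

    def test_degenerate_residual_weights(self, rng):
        """omega -> (1,0) and F_multi zeroed leaves exactly X_i'."""
        nn.init.seed_all(6)
        stfu = STFU()
        stfu.omega_logits.data = np.array([30.0, -30.0], dtype=np.float32)
        for i in range(3):
            br = getattr(stfu.couple, f"branch{i}")
            br.weight.data[:] = 0
            br.bias.data[:] = 0
        shallow = Tensor(rng.standard_normal((1, 96, 16, 16)).astype(np.float32))
        deep = Tensor(rng.standard_normal((1, 96, 8, 8)).astype(np.float32))
        x_i, _ = stfu.align(shallow, deep)
        out = stfu(shallow, deep)
        assert np.allclose(out.data, x_i.data, atol=1e-5)

    def test_softmax_constraints_hold_after_optimizer_steps(self, rng):
        nn.init.seed_all(7)
        stfu = STFU()
        opt = nn.AdamW(stfu.parameters(), lr=1e-2)
        shallow = Tensor(rng.standard_normal((1, 96, 16, 16)).astype(np.float32))
        deep = Tensor(rng.standard_normal((1, 96, 8, 8)).astype(np.float32))
        for _ in range(3):
            loss = (stfu(shallow, deep) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        alpha = stfu.couple.branch_weights().data
        omega = stfu.residual_weights().data
        assert abs(alpha.sum() - 1) < 1e-6 and (alpha >= 0).all()
        assert abs(omega.sum() - 1) < 1e-6 and (omega >= 0).all()

    def test_instances_share_no_parameters(self):
        nn.init.seed_all(8)
        a, b = STFU(), STFU()
        ids_a = {id(p) for _, p in a.named_parameters()}
        ids_b = {id(p) for _, p in b.named_parameters()}
        assert not ids_a & ids_b
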