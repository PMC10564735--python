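"""The attention-residual fusion block: gating, residual path, downscale.

The central check re-states the fusion formula
F_hat = (1 + Att) * (Phi(concat) + F_j) entry by entry outside the
module and compares the block's output against it.
"""

import math

import numpy as np
import pytest

from armnet import (ARMBlock, arm_downscale, arm_forward, arm_fuse,
                    attention_map, concat_maps, residual_branch)
from armnet import nn
from armnet.exceptions import ConfigError, InvalidInputError, ShapeError


def make_block(ci=2, cj=3, co=4, seed=0, **kw):
    return ARMBlock(ci, cj, co, init_seed=seed, **kw).eval()


def random_maps(rng, ci=2, cj=3, side=4, n=1):
    fi = rng.normal(size=(n, ci, side, side)).astype(np.float32)
    fj = rng.normal(size=(n, cj, side, side)).astype(np.float32)
    return fi, fj


class TestConcat:
    def test_shape_arithmetic(self, rng):
        fi, fj = random_maps(rng, ci=2, cj=3, side=4)
        out = concat_maps(fi, fj)
        assert out.shape == (1, 5, 4, 4)

    def test_value_preservation_against_zeros(self, rng):
        fi, _ = random_maps(rng, ci=2, cj=2)
        out = concat_maps(fi, np.zeros_like(fi))
        np.testing.assert_array_equal(out.data[:, :2], fi)
        np.testing.assert_array_equal(out.data[:, 2:], 0)

    def test_index_bookkeeping_oracle(self, rng):
        fi, fj = random_maps(rng, ci=3, cj=2, side=3)
        out = concat_maps(fi, fj).data
        for c in range(5):
            for y in range(3):
                for x in range(3):
                    src = fi[0, c, y, x] if c < 3 else fj[0, c - 3, y, x]
                    assert out[0, c, y, x] == src

    def test_spatial_mismatch_raises_named_error(self, rng):
        fi = rng.normal(size=(1, 2, 4, 4))
        fj = rng.normal(size=(1, 3, 8, 8))
        with pytest.raises(ShapeError, match="4.*8|8.*4"):
            concat_maps(fi, fj)


class TestAttention:
    def test_zero_initialized_gate_is_neutral_half(self, rng):
        block = make_block()
        fi, fj = random_maps(rng)
        att = attention_map(block, concat_maps(fi, fj)).data
        np.testing.assert_allclose(att, 0.5, atol=1e-6)

    def test_saturation_limits(self):
        block = make_block(ci=1, cj=1)
        block.att_conv.bias.data[:] = 20.0
        cat = np.zeros((1, 2, 2, 2), dtype=np.float32)
        assert attention_map(block, cat).data == pytest.approx(1.0, abs=1e-8)
        block.att_conv.bias.data[:] = -20.0
        assert attention_map(block, cat).data == pytest.approx(0.0, abs=1e-8)

    def test_fixed_d_matrix_matches_scalar_sigmoid(self):
        # raw mode uses F_j's slice of the concatenation as D directly
        block = make_block(ci=1, cj=1, attention="raw")
        d = np.array([[0.5, -0.5], [1.0, -1.0]], dtype=np.float32)
        cat = np.stack([np.zeros_like(d), d])[None]
        att = attention_map(block, cat).data[0, 0]
        for y in range(2):
            for x in range(2):
                expected = 1.0 / (1.0 + math.exp(-float(d[y, x])))
                assert att[y, x] == pytest.approx(expected, rel=1e-6)

    def test_attention_strictly_inside_unit_interval(self, rng):
        block = make_block(seed=9)
        for p in block.att_conv.parameters():
            p.data = rng.normal(size=p.data.shape).astype(np.float32)
        fi, fj = random_maps(rng)
        att = attention_map(block, concat_maps(fi, fj)).data
        assert np.all(att > 0) and np.all(att < 1)

    def test_channel_mismatch_rejected(self, rng):
        block = make_block(ci=2, cj=3)
        with pytest.raises(ShapeError):
            attention_map(block, rng.normal(size=(1, 4, 4, 4)))


class TestResidualBranch:
    def test_zero_phi_weights_give_identity(self, rng):
        block = make_block()
        for p in block.phi.parameters():
            p.data[...] = 0
        fi, fj = random_maps(rng)
        out = residual_branch(block, concat_maps(fi, fj), fj)
        np.testing.assert_allclose(out.data, fj, atol=1e-6)

    def test_zero_skip_gives_pure_phi(self, rng):
        block = make_block()
        fi, fj = random_maps(rng)
        cat = concat_maps(fi, np.zeros_like(fj))
        out = residual_branch(block, cat, np.zeros_like(fj))
        np.testing.assert_allclose(out.data, block.phi(cat).data, atol=1e-6)

    def test_first_conv_matches_direct_convolution_oracle(self):
        # Collapse Phi to relu(conv1): second conv = centered delta kernel,
        # projection = identity, normalization at its neutral settings.
        block = make_block(ci=1, cj=1, co=1)
        w = np.array([[0.0, 1.0, 0.0],
                      [-1.0, 2.0, 1.0],
                      [0.0, -1.0, 0.0]], dtype=np.float32)
        conv1, _, _, conv2, _, proj = list(block.phi)
        conv1.weight.data = np.zeros((1, 2, 3, 3), dtype=np.float32)
        conv1.weight.data[0, 1] = w  # read only the F_j slice
        conv1.bias.data[:] = 0
        conv2.weight.data = np.zeros((1, 1, 3, 3), dtype=np.float32)
        conv2.weight.data[0, 0, 1, 1] = 1.0
        conv2.bias.data[:] = 0
        proj.weight.data = np.ones((1, 1, 1, 1), dtype=np.float32)
        proj.bias.data[:] = 0

        fj = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)[None, None]
        fi = np.zeros_like(fj)
        cat = concat_maps(fi, fj)
        # explicit zero-padded 3x3 convolution arithmetic
        padded = np.pad(fj[0, 0], 1)
        expected = np.zeros((2, 2))
        for y in range(2):
            for x in range(2):
                expected[y, x] = (padded[y:y + 3, x:x + 3] * w).sum()
        expected = np.maximum(expected, 0)  # rectifier between the convs
        out = residual_branch(block, cat, np.zeros_like(fj))
        np.testing.assert_allclose(out.data[0, 0], expected, rtol=1e-4,
                                   atol=1e-5)


class TestFuse:
    def test_neutral_gate_zero_phi_gives_1p5_fj(self, rng):
        block = make_block()
        for p in block.phi.parameters():
            p.data[...] = 0
        fi, fj = random_maps(rng)
        out = arm_fuse(block, fi, fj)
        np.testing.assert_allclose(out.data, 1.5 * fj, rtol=1e-5, atol=1e-6)

    def test_zero_residual_annihilates_output(self, rng):
        block = make_block()
        for p in block.phi.parameters():
            p.data[...] = 0
        for p in block.att_conv.parameters():
            p.data = rng.normal(size=p.data.shape).astype(np.float32)
        fi = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        fj = np.zeros((1, 3, 4, 4), dtype=np.float32)
        out = arm_fuse(block, fi, fj)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_entrywise_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ci, cj = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        side = int(rng.integers(1, 5)) * 2
        block = ARMBlock(ci, cj, cj, init_seed=seed).eval()
        for p in block.att_conv.parameters():
            p.data = rng.normal(scale=0.5, size=p.data.shape).astype(np.float32)
        fi, fj = random_maps(rng, ci, cj, side, n=2)
        cat = concat_maps(fi, fj)
        att = block.attention_map(cat).data
        phi = block.phi(cat).data
        expected = np.empty_like(phi)
        for n in range(2):
            for c in range(cj):
                for y in range(side):
                    for x in range(side):
                        r = phi[n, c, y, x] + fj[n, c, y, x]
                        expected[n, c, y, x] = (1.0 + att[n, c, y, x]) * r
        out = arm_fuse(block, fi, fj).data
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_gate_output_between_1x_and_2x_residual(self, rng):
        block = make_block(seed=4)
        fi, fj = random_maps(rng)
        cat = concat_maps(fi, fj)
        r = residual_branch(block, cat, fj).data
        out = arm_fuse(block, fi, fj).data
        pos = r > 0
        assert np.all(out[pos] >= r[pos] - 1e-6)
        assert np.all(out[pos] <= 2 * r[pos] + 1e-6)

    def test_gating_is_monotone_in_d(self, rng):
        block = make_block(ci=1, cj=1)
        fi = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        fj = np.abs(rng.normal(size=(1, 1, 4, 4))).astype(np.float32) + 0.1
        for p in block.phi.parameters():
            p.data[...] = 0  # residual output = fj > 0 everywhere
        outputs = []
        for bias in (-2.0, 0.0, 2.0):
            block.att_conv.bias.data[:] = bias
            outputs.append(arm_fuse(block, fi, fj).data.copy())
        assert np.all(outputs[0] < outputs[1])
        assert np.all(outputs[1] < outputs[2])

    def test_identity_limit_suppressed_attention(self, rng):
        block = make_block(seed=2)
        block.att_conv.bias.data[:] = -30.0
        fi, fj = random_maps(rng)
        cat = concat_maps(fi, fj)
        r = residual_branch(block, cat, fj).data
        out = arm_fuse(block, fi, fj).data
        np.testing.assert_allclose(out, r, atol=1e-6)


class TestDownscale:
    def test_halves_the_side(self, rng):
        block = make_block(ci=2, cj=3, co=5)
        fused = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
        assert arm_downscale(block, fused).shape == (1, 5, 4, 4)

    def test_odd_side_rejected(self, rng):
        block = make_block()
        with pytest.raises(InvalidInputError):
            arm_downscale(block, rng.normal(size=(1, 3, 7, 7)))

    def test_zero_weights_give_zero_output(self, rng):
        block = make_block(ci=1, cj=2, co=3)
        for p in block.down_main.parameters():
            p.data[...] = 0
        for p in block.down_short.parameters():
            p.data[...] = 0
        out = arm_downscale(block, rng.normal(size=(1, 2, 4, 4)))
        assert out.shape == (1, 3, 2, 2)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_stride2_arithmetic_by_hand(self):
        # 1-channel 2x2 input; main 3x3 stride-2 pad-1 conv sees the input
        # through its lower-right 2x2 taps; shortcut 1x1 stride 2 picks
        # the top-left pixel
        block = make_block(ci=1, cj=1, co=1)
        main_conv = list(block.down_main)[0]
        short_conv = list(block.down_short)[0]
        wm = np.arange(9, dtype=np.float32).reshape(3, 3)
        main_conv.weight.data = wm[None, None]
        main_conv.bias.data[:] = 0
        short_conv.weight.data = np.array([[[[2.0]]]], dtype=np.float32)
        short_conv.bias.data[:] = 0
        x = np.array([[5.0, 6.0], [7.0, 8.0]], dtype=np.float32)[None, None]
        # padded input window at the single output position:
        # [[0,0,0],[0,5,6],[0,7,8]] . wm = 5*4+6*5+7*7+8*8
        expected_main = 5 * 4 + 6 * 5 + 7 * 7 + 8 * 8
        expected = expected_main + 2.0 * 5.0
        out = arm_downscale(block, x)
        assert out.shape == (1, 1, 1, 1)
        assert out.data[0, 0, 0, 0] == pytest.approx(expected, rel=1e-4)


class TestForward:
    def test_shape_contract(self, rng):
        block = ARMBlock(4, 4, 6, init_seed=1).eval()
        fi = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        fj = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
        assert arm_forward(block, fi, fj).shape == (2, 6, 4, 4)

    def test_gradient_reaches_every_parameter_group(self, rng):
        block = ARMBlock(2, 3, 4, init_seed=0)
        block.train()
        fi, fj = random_maps(rng, n=4, side=4)
        out = arm_forward(block, nn.Tensor(fi), nn.Tensor(fj))
        loss = nn.cross_entropy(nn.global_avg_pool(out), np.array([0, 1, 2, 3]))
        loss.backward()
        for group in (block.phi, block.att_conv, block.down_main,
                      block.down_short):
            norms = [float(np.abs(p.grad).sum()) for p in group.parameters()
                     if p.grad is not None]
            assert norms and sum(norms) > 0

    def test_forward_equals_chained_sub_operations(self, rng):
        block = make_block(seed=6)
        fi, fj = random_maps(rng, side=6)
        chained = arm_downscale(block, arm_fuse(block, fi, fj))
        np.testing.assert_array_equal(arm_forward(block, fi, fj).data,
                                      chained.data)

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigError):
            ARMBlock(0, 3, 4)
        with pytest.raises(ConfigError):
            ARMBlock(2, 3, 4, attention="spatial")
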