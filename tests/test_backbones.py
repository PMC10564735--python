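"""Feature pyramids, the fusion cascade and classifier construction."""

import numpy as np
import pytest

from armnet import (ARMBlock, BackboneSpec, aggregate_with_arm, arm_forward,
                    build_backbone, build_classifier, extract_pyramid,
                    fuse_final, upsample2x)
from armnet import nn
from armnet.backbones import FAMILIES, ARMClassifier, BaselineClassifier
from armnet.exceptions import ConfigError, InvalidInputError, ShapeError


def tiny_pyramid(side=32, seed=0, batch=1):
    spec = BackboneSpec(family="tiny", num_classes=4, init_seed=seed)
    backbone = build_backbone(spec).eval()
    x = np.random.default_rng(seed).normal(
        size=(batch, 3, side, side)).astype(np.float32)
    return backbone, x, extract_pyramid(backbone, x, source="tiny")


class TestExtractPyramid:
    def test_tiny_32_input_halving_law(self):
        _, _, pyr = tiny_pyramid(32)
        assert pyr.sides == (8, 4, 2, 1)

    def test_tiny_224_input(self):
        _, _, pyr = tiny_pyramid(224)
        assert pyr.sides == (56, 28, 14, 7)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_every_family_obeys_halving_at_side_64(self, family):
        spec = BackboneSpec(family=family, num_classes=4, init_seed=0)
        backbone = build_backbone(spec).eval()
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        pyr = extract_pyramid(backbone, x, source=family)
        assert pyr.sides == (16, 8, 4, 2)
        assert pyr.channels == backbone.tap_channels

    def test_indivisible_side_rejected(self):
        backbone = build_backbone(BackboneSpec(family="tiny", num_classes=4))
        with pytest.raises(InvalidInputError):
            extract_pyramid(backbone, np.zeros((1, 3, 60, 60),
                                               dtype=np.float32))

    def test_taps_equal_sequential_reference_forward(self):
        backbone, x, pyr = tiny_pyramid(32, seed=7)
        t0 = backbone.stem(nn.Tensor(x))
        t1 = backbone.stage2(t0)
        t2 = backbone.stage3(t1)
        t3 = backbone.stage4(t2)
        for tap, ref in zip(pyr.maps, (t0, t1, t2, t3)):
            np.testing.assert_array_equal(tap.data, ref.data)


class TestUpsample2x:
    def test_constant_map_stays_constant(self):
        out = upsample2x(np.full((1, 2, 7, 7), 3.25, dtype=np.float32))
        assert out.shape == (1, 2, 14, 14)
        np.testing.assert_allclose(out.data, 3.25, rtol=1e-6)

    def test_hand_computed_bilinear_grid(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float64)[None, None]
        out = upsample2x(x).data[0, 0]
        # half-pixel centers: output samples at -0.25, 0.25, 0.75, 1.25
        expected = np.array([
            [1.0, 1.25, 1.75, 2.0],
            [1.5, 1.75, 2.25, 2.5],
            [2.5, 2.75, 3.25, 3.5],
            [3.0, 3.25, 3.75, 4.0],
        ])
        np.testing.assert_allclose(out, expected, rtol=1e-6)


class TestAggregate:
    def make_blocks(self, channels, seed=0):
        c = channels
        return [ARMBlock(c[1], c[0], c[1], init_seed=seed),
                ARMBlock(c[2], c[1], c[2], init_seed=seed + 1),
                ARMBlock(c[3], c[2], c[3], init_seed=seed + 2)]

    def test_tiny_pyramid_aggregates_to_side_1(self):
        backbone, _, pyr = tiny_pyramid(32)
        blocks = [b.eval() for b in self.make_blocks(backbone.tap_channels)]
        out = aggregate_with_arm(pyr, blocks)
        assert out.shape[1:] == (backbone.tap_channels[3], 1, 1)

    def test_stage_outputs_equal_chained_arm_forwards(self):
        backbone, _, pyr = tiny_pyramid(64, seed=3)
        blocks = [b.eval() for b in self.make_blocks(backbone.tap_channels, 5)]
        out = aggregate_with_arm(pyr, blocks)
        running = pyr.maps[0]
        for k, block in enumerate(blocks):
            running = arm_forward(block, upsample2x(pyr.maps[k + 1]), running)
        np.testing.assert_array_equal(out.data, running.data)

    def test_wrong_block_count_rejected(self):
        _, _, pyr = tiny_pyramid(32)
        with pytest.raises(ConfigError):
            aggregate_with_arm(pyr, [])

    def test_channel_inconsistency_rejected(self):
        _, _, pyr = tiny_pyramid(32)
        bad = [ARMBlock(99, 16, 32), ARMBlock(64, 32, 64),
               ARMBlock(128, 64, 128)]
        with pytest.raises(ConfigError):
            aggregate_with_arm(pyr, bad)


class TestFuseFinal:
    def test_additive_identity(self, rng):
        m = rng.normal(size=(1, 4, 7, 7)).astype(np.float32)
        out = fuse_final(np.zeros_like(m), m)
        np.testing.assert_array_equal(out.data, m)

    def test_doubling(self, rng):
        m = rng.normal(size=(1, 4, 7, 7)).astype(np.float32)
        np.testing.assert_allclose(fuse_final(m, m).data, 2 * m, rtol=1e-6)

    def test_entrywise_sum_oracle(self, rng):
        a = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        b = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        out = fuse_final(a, b).data
        for c in range(2):
            for y in range(3):
                for x in range(3):
                    assert out[0, c, y, x] == a[0, c, y, x] + b[0, c, y, x]

    def test_irreconcilable_shapes_rejected(self, rng):
        with pytest.raises(ShapeError):
            fuse_final(rng.normal(size=(1, 2, 7, 7)),
                       rng.normal(size=(1, 3, 7, 7)))


class TestBuildClassifier:
    def test_score_grid_shape_38_classes(self):
        model = build_classifier(BackboneSpec(
            family="tiny", num_classes=38, arm_enabled=True, init_seed=0))
        model.eval()
        x = np.random.default_rng(0).normal(size=(4, 3, 32, 32)).astype(np.float32)
        logits = model(x)
        assert logits.shape == (4, 38)

    def test_softmax_normalizes(self):
        model = build_classifier(BackboneSpec(
            family="tiny", num_classes=5, arm_enabled=True, init_seed=1))
        model.eval()
        x = np.random.default_rng(1).normal(size=(3, 3, 32, 32)).astype(np.float32)
        z = model(x).data
        probs = np.exp(z - z.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_param_count_difference_is_exactly_the_fusion_path(self):
        arm = build_classifier(BackboneSpec(
            family="tiny", num_classes=4, arm_enabled=True, init_seed=0))
        base = build_classifier(BackboneSpec(
            family="tiny", num_classes=4, arm_enabled=False, init_seed=0))
        extra = sum(b.num_params() for b in arm.blocks)
        assert arm.num_params() - base.num_params() == extra

    def test_drop_in_property_same_io_shapes(self):
        x = np.random.default_rng(2).normal(size=(2, 3, 32, 32)).astype(np.float32)
        outs = []
        for enabled in (False, True):
            model = build_classifier(BackboneSpec(
                family="tiny", num_classes=6, arm_enabled=enabled, init_seed=0))
            model.eval()
            outs.append(model(x).shape)
        assert outs[0] == outs[1] == (2, 6)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            BackboneSpec(family="alexnet", num_classes=4)

    def test_one_optimizer_step_moves_attention_parameters(self):
        model = build_classifier(BackboneSpec(
            family="tiny", num_classes=4, arm_enabled=True, init_seed=0))
        model.train()
        x = np.random.default_rng(3).normal(size=(4, 3, 32, 32)).astype(np.float32)
        y = np.array([0, 1, 2, 3])
        opt = nn.Adam(model.parameters(), lr=1e-3)
        loss = nn.cross_entropy(model(x), y)
        opt.zero_grad()
        loss.backward()
        att_grads = [float(np.abs(p.grad).sum())
                     for b in model.blocks for p in b.att_conv.parameters()]
        assert sum(att_grads) > 0
        before = [p.data.copy() for b in model.blocks
                  for p in b.att_conv.parameters()]
        opt.step()
        after = [p.data for b in model.blocks for p in b.att_conv.parameters()]
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_manifest_reports_block_configuration(self):
        model = build_classifier(BackboneSpec(
            family="tiny", num_classes=4, arm_enabled=True, init_seed=0))
        manifest = model.build_manifest()
        assert manifest["family"] == "tiny"
        assert manifest["tap_channels"] == [16, 32, 64, 128]
        assert len(manifest["arm_blocks"]) == 3
        assert manifest["total_params"] == model.num_params()
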