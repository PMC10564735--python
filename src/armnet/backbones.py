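"""Backbone networks, feature pyramids and the fusion cascade.

Every family taps four internal activations at spatial sides
(input/4, input/8, input/16, input/32) — i.e. 56/28/14/7 for a 224
input.  The cascade then walks the pyramid shallow-to-deep: at each
stage the next deeper map is upsampled x2, fused with the running map
by an :class:`~armnet.arm.ARMBlock`, and the block's internal stride-2
path returns the result to the deeper map's native side.  The stage-3
output (side input/32) is summed pixel-wise with the backbone's last
feature layer before the classification head.

Families:

``vgg16``      plain 3x3 conv stacks, taps after pooling stages 2-5
               (channels 128/256/512/512)
``resnet50``   bottleneck stages [3,4,6,3], taps after each stage
               (256/512/1024/2048)
``googlenet``  inception-v1 modules, taps after the conv2 block and
               inception groups 3/4/5 (192/480/832/1024)
``tiny``       a small 4-stage convnet (16/32/64/128) for synthetic
               experiments; accepts any input side divisible by 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .arm import ARMBlock
from .exceptions import ConfigError, InvalidInputError, ShapeError
from .nn import Tensor

__all__ = [
    "PyramidFeatures", "BackboneSpec", "build_backbone", "extract_pyramid",
    "upsample2x", "aggregate_with_arm", "fuse_final", "build_classifier",
    "ARMClassifier", "BaselineClassifier", "FAMILIES",
]

FAMILIES = ("vgg16", "googlenet", "resnet50", "tiny")


@dataclass
class PyramidFeatures:
    """Ordered four-level feature pyramid (shallow to deep)."""

    maps: list
    source: str

    def __post_init__(self):
        if len(self.maps) != 4:
            raise ShapeError(f"a pyramid has exactly 4 levels, got {len(self.maps)}")
        sides = [m.shape[-1] for m in self.maps]
        for a, b in zip(sides, sides[1:]):
            if a != 2 * b:
                raise ShapeError(f"pyramid sides {sides} violate the halving law")

    @property
    def sides(self) -> tuple:
        return tuple(m.shape[-1] for m in self.maps)

    @property
    def channels(self) -> tuple:
        return tuple(m.shape[1] for m in self.maps)


@dataclass(frozen=True)
class BackboneSpec:
    family: str = "tiny"
    pretrained: str | None = None  # optional checkpoint path for warm-starting
    num_classes: int = 2
    arm_enabled: bool = True
    init_seed: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")


# ---------------------------------------------------------------------
# backbone families
# ---------------------------------------------------------------------

class _ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, k, stride=1, padding=0, rng=None, bn=True):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride=stride, padding=padding,
                              rng=rng, bias=not bn)
        self.bn = nn.BatchNorm2d(c_out) if bn else nn.Identity()
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class TinyBackbone(nn.Module):
    tap_channels = (16, 32, 64, 128)

    def __init__(self, rng=None):
        super().__init__()
        c = self.tap_channels
        self.stem = nn.Sequential([
            _ConvBNReLU(3, c[0], 3, stride=2, padding=1, rng=rng),
            _ConvBNReLU(c[0], c[0], 3, stride=2, padding=1, rng=rng),
        ])
        self.stage2 = _ConvBNReLU(c[0], c[1], 3, stride=2, padding=1, rng=rng)
        self.stage3 = _ConvBNReLU(c[1], c[2], 3, stride=2, padding=1, rng=rng)
        self.stage4 = _ConvBNReLU(c[2], c[3], 3, stride=2, padding=1, rng=rng)

    def forward(self, x):
        t0 = self.stem(x)
        t1 = self.stage2(t0)
        t2 = self.stage3(t1)
        t3 = self.stage4(t2)
        return [t0, t1, t2, t3]


class VGG16Backbone(nn.Module):
    """13 convolutional layers in five pooled blocks (no normalization)."""

    tap_channels = (128, 256, 512, 512)
    _cfg = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))

    def __init__(self, rng=None):
        super().__init__()
        blocks = []
        c_in = 3
        for widths in self._cfg:
            layers = []
            for c_out in widths:
                layers += [_ConvBNReLU(c_in, c_out, 3, padding=1, rng=rng, bn=False)]
                c_in = c_out
            layers += [nn.MaxPool2d()]
            blocks.append(nn.Sequential(layers))
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x):
        taps = []
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i >= 1:  # taps after pooled blocks 2..5
                taps.append(x)
        return taps


class _Bottleneck(nn.Module):
    def __init__(self, c_in, width, stride=1, rng=None):
        super().__init__()
        c_out = width * 4
        self.a = _ConvBNReLU(c_in, width, 1, rng=rng)
        self.b = _ConvBNReLU(width, width, 3, stride=stride, padding=1, rng=rng)
        self.c_conv = nn.Conv2d(width, c_out, 1, rng=rng, bias=False)
        self.c_bn = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.short = nn.Sequential([
                nn.Conv2d(c_in, c_out, 1, stride=stride, rng=rng, bias=False),
                nn.BatchNorm2d(c_out),
            ])
        else:
            self.short = nn.Identity()
        self.act = nn.ReLU()

    def forward(self, x):
        y = self.c_bn(self.c_conv(self.b(self.a(x))))
        return self.act(y + self.short(x))


class ResNet50Backbone(nn.Module):
    tap_channels = (256, 512, 1024, 2048)
    _layout = ((3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2))

    def __init__(self, rng=None):
        super().__init__()
        self.stem = nn.Sequential([
            _ConvBNReLU(3, 64, 7, stride=2, padding=3, rng=rng),
            nn.MaxPool2d(),
        ])
        stages = []
        c_in = 64
        for n_blocks, width, stride in self._layout:
            blocks = []
            for b in range(n_blocks):
                blocks.append(_Bottleneck(c_in, width,
                                          stride=stride if b == 0 else 1, rng=rng))
                c_in = width * 4
            stages.append(nn.Sequential(blocks))
        self.stages = nn.ModuleList(stages)

    def forward(self, x):
        x = self.stem(x)
        taps = []
        for stage in self.stages:
            x = stage(x)
            taps.append(x)
        return taps


class _Inception(nn.Module):
    def __init__(self, c_in, c1, c3r, c3, c5r, c5, cp, rng=None):
        super().__init__()
        self.b1 = _ConvBNReLU(c_in, c1, 1, rng=rng)
        self.b3 = nn.Sequential([_ConvBNReLU(c_in, c3r, 1, rng=rng),
                                 _ConvBNReLU(c3r, c3, 3, padding=1, rng=rng)])
        self.b5 = nn.Sequential([_ConvBNReLU(c_in, c5r, 1, rng=rng),
                                 _ConvBNReLU(c5r, c5, 5, padding=2, rng=rng)])
        self.bp_conv = _ConvBNReLU(c_in, cp, 1, rng=rng)

    def forward(self, x):
        pool = nn.maxpool2d(x, kernel_size=3, stride=1, padding=1)
        return nn.concat([self.b1(x), self.b3(x), self.b5(x),
                          self.bp_conv(pool)], axis=1)


class GoogLeNetBackbone(nn.Module):
    tap_channels = (192, 480, 832, 1024)
    _inception_cfg = {
        "i3": ((192, 64, 96, 128, 16, 32, 32), (256, 128, 128, 192, 32, 96, 64)),
        "i4": ((480, 192, 96, 208, 16, 48, 64), (512, 160, 112, 224, 24, 64, 64),
               (512, 128, 128, 256, 24, 64, 64), (512, 112, 144, 288, 32, 64, 64),
               (528, 256, 160, 320, 32, 128, 128)),
        "i5": ((832, 256, 160, 320, 32, 128, 128), (832, 384, 192, 384, 48, 128, 128)),
    }

    def __init__(self, rng=None):
        super().__init__()
        self.stem = nn.Sequential([
            _ConvBNReLU(3, 64, 7, stride=2, padding=3, rng=rng),
            nn.MaxPool2d(),
            _ConvBNReLU(64, 64, 1, rng=rng),
            _ConvBNReLU(64, 192, 3, padding=1, rng=rng),
        ])
        self.pool = nn.MaxPool2d()
        for name, cfgs in self._inception_cfg.items():
            setattr(self, name, nn.Sequential([_Inception(*cfg, rng=rng)
                                               for cfg in cfgs]))

    def forward(self, x):
        t0 = self.stem(x)
        t1 = self.i3(self.pool(t0))
        t2 = self.i4(self.pool(t1))
        t3 = self.i5(self.pool(t2))
        return [t0, t1, t2, t3]


_FAMILY_CLASSES = {
    "tiny": TinyBackbone,
    "vgg16": VGG16Backbone,
    "resnet50": ResNet50Backbone,
    "googlenet": GoogLeNetBackbone,
}


def build_backbone(spec: BackboneSpec) -> nn.Module:
    rng = np.random.default_rng(spec.init_seed)
    return _FAMILY_CLASSES[spec.family](rng=rng)


# ---------------------------------------------------------------------
# pyramid / cascade operations
# ---------------------------------------------------------------------

def _as_input(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    if t.ndim != 4 or t.shape[1] != 3:
        raise InvalidInputError(f"expected (N,3,S,S) or (3,S,S) input, got {t.shape}")
    return t


def extract_pyramid(backbone, x, source: str = "") -> PyramidFeatures:
    """Run a backbone and collect its four tap activations."""
    if isinstance(backbone, BackboneSpec):
        source = source or backbone.family
        backbone = build_backbone(backbone)
    t = _as_input(x)
    if t.shape[2] % 32:
        raise InvalidInputError(
            f"input side {t.shape[2]} is not divisible by 32")
    return PyramidFeatures(maps=backbone(t), source=source or type(backbone).__name__)


def upsample2x(fmap) -> Tensor:
    """Bilinear x2 spatial upsampling, channels unchanged."""
    t = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return nn.upsample_bilinear(t, factor=2)


def aggregate_with_arm(pyramid: PyramidFeatures, blocks) -> Tensor:
    """Three-stage shallow-to-deep cascade; returns the deepest-side map.

    Stage k upsamples pyramid level k+1 to the running map's side,
    fuses, and downscales — so the output side equals level k+1's side;
    after stage 3 that is the last pyramid level's side (7 for 224).
    """
    blocks = list(blocks)
    if len(blocks) != 3:
        raise ConfigError(f"the cascade needs exactly 3 fusion blocks, got {len(blocks)}")
    running = pyramid.maps[0]
    for k, block in enumerate(blocks):
        deeper = pyramid.maps[k + 1]
        f_i = upsample2x(deeper)
        if f_i.shape[1] != block.in_channels_i or running.shape[1] != block.in_channels_j:
            raise ConfigError(
                f"stage {k + 1} block expects channels "
                f"({block.in_channels_i}, {block.in_channels_j}), got "
                f"({f_i.shape[1]}, {running.shape[1]})")
        running = block(f_i, running)
    return running


def fuse_final(aggregated, last_layer) -> Tensor:
    """Pixel-wise sum of the cascade output and the last backbone map."""
    a = aggregated if isinstance(aggregated, Tensor) else Tensor(aggregated)
    b = last_layer if isinstance(last_layer, Tensor) else Tensor(last_layer)
    if a.shape != b.shape:
        raise ShapeError(
            f"cannot sum maps of shapes {a.shape} and {b.shape}")
    return a + b


# ---------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------

class BaselineClassifier(nn.Module):
    """Backbone + global average pooling + linear head."""

    def __init__(self, spec: BackboneSpec):
        super().__init__()
        rng = np.random.default_rng(spec.init_seed)
        self.spec = spec
        self.backbone = _FAMILY_CLASSES[spec.family](rng=rng)
        self.head = nn.Linear(self.backbone.tap_channels[3], spec.num_classes, rng=rng)
        self.activations: dict = {}

    def forward(self, x, capture: bool = False):
        taps = self.backbone(_as_input(x))
        pooled = nn.global_avg_pool(taps[3])
        logits = self.head(pooled)
        if capture:
            self.activations = _capture_taps(taps)
        return logits


class ARMClassifier(nn.Module):
    """Backbone + fusion cascade + pixel-wise final sum + linear head."""

    def __init__(self, spec: BackboneSpec):
        super().__init__()
        rng = np.random.default_rng(spec.init_seed)
        self.spec = spec
        self.backbone = _FAMILY_CLASSES[spec.family](rng=rng)
        c = self.backbone.tap_channels
        seeds = (None,) * 3 if spec.init_seed is None else \
            tuple(int(s) for s in np.random.default_rng(spec.init_seed).integers(
                0, 2**31 - 1, size=3))
        self.blocks = nn.ModuleList([
            ARMBlock(c[1], c[0], c[1], init_seed=seeds[0]),
            ARMBlock(c[2], c[1], c[2], init_seed=seeds[1]),
            ARMBlock(c[3], c[2], c[3], init_seed=seeds[2]),
        ])
        # cascade output channels == c[3] by construction, so no projection
        # is needed for the pixel-wise sum with the last backbone layer
        self.head = nn.Linear(c[3], spec.num_classes, rng=rng)
        self.activations: dict = {}

    def forward(self, x, capture: bool = False):
        taps = self.backbone(_as_input(x))
        pyramid = PyramidFeatures(maps=taps, source=self.spec.family)
        aggregated = aggregate_with_arm(pyramid, list(self.blocks))
        fused = fuse_final(aggregated, taps[3])
        pooled = nn.global_avg_pool(fused)
        logits = self.head(pooled)
        if capture:
            self.activations = _capture_taps(taps)
            self.activations["arm_aggregated"] = aggregated.data.copy()
            self.activations["final_fused"] = fused.data.copy()
        return logits

    def build_manifest(self) -> dict:
        c = self.backbone.tap_channels
        return {
            "family": self.spec.family,
            "num_classes": self.spec.num_classes,
            "tap_channels": list(c),
            "arm_blocks": [
                {"in_channels_i": b.in_channels_i, "in_channels_j": b.in_channels_j,
                 "out_channels": b.out_channels, "params": b.num_params()}
                for b in self.blocks],
            "total_params": self.num_params(),
        }


def _capture_taps(taps) -> dict:
    return {f"tap{m.shape[-1]}": m.data.copy() for m in taps}


def build_classifier(spec: BackboneSpec) -> nn.Module:
    """Build a baseline or fusion-enhanced classifier per the spec."""
    model = ARMClassifier(spec) if spec.arm_enabled else BaselineClassifier(spec)
    if spec.pretrained:
        from .training import load_checkpoint
        load_checkpoint(model, spec.pretrained)
    return model
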