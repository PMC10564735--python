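"""The attention-residual fusion block for adjacent-scale feature maps.

Given two same-side feature maps F_i (the upsampled deeper level) and
F_j (the shallower level carrying the skip connection), the block
computes

    F_hat = (1 + Att[concat(F_i, F_j)]) * (Phi[concat(F_i, F_j)] + F_j)

where Phi is a small residual function (3x3 conv -> BN -> ReLU -> 3x3
conv -> BN -> 1x1 projection to F_j's channel count) and Att is an
element-wise logistic sigmoid of a learned 1x1 convolution D of the
concatenated map.  The attention gate re-weights the residual output
R = Phi(concat) + F_j multiplicatively between 1x and 2x, so a
zero-initialized gate (Att = 0.5 everywhere) starts training at a
neutral 1.5x scaling and the gate can only emphasize, never erase,
the residual features.  A stride-2 residual block then halves the
spatial side so the fused map re-enters the pyramid at the deeper
level's resolution.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .exceptions import ConfigError, InvalidInputError, ShapeError
from .nn import Tensor

__all__ = [
    "ARMBlock", "concat_maps", "attention_map", "residual_branch",
    "arm_fuse", "arm_downscale", "arm_forward",
]


def _as_batch(x) -> Tensor:
    """Accept (C, S, S) or (N, C, S, S); return a 4-D Tensor."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    if t.ndim != 4:
        raise ShapeError(f"expected a 3-D or 4-D feature map, got shape {t.shape}")
    if t.shape[2] != t.shape[3]:
        raise ShapeError(f"feature maps must be square, got {t.shape[2]}x{t.shape[3]}")
    if not np.all(np.isfinite(t.data)):
        raise InvalidInputError("feature map contains non-finite entries")
    return t


def concat_maps(f_i, f_j) -> Tensor:
    """Channel-axis concatenation; F_i's channels come first."""
    a, b = _as_batch(f_i), _as_batch(f_j)
    if a.shape[2] != b.shape[2]:
        raise ShapeError(
            f"spatial sides differ: F_i is {a.shape[2]}, F_j is {b.shape[2]}")
    return nn.concat([a, b], axis=1)


class ARMBlock(nn.Module):
    """Parameterized fusion unit: residual branch, attention gate, downscale.

    Parameters
    ----------
    in_channels_i, in_channels_j:
        Channel counts of the two inputs; Phi and the gate both map to
        ``in_channels_j`` so the ``+ F_j`` skip and the element-wise
        product are well defined.
    out_channels:
        Channel count after the stride-2 downscale path.
    attention:
        ``"learned"`` (default) derives the pre-sigmoid map D from a
        zero-initialized 1x1 convolution of the concatenated features;
        ``"raw"`` uses F_j's slice of the concatenation as D directly
        (a parameter-free gate, kept for comparison).
    downscale:
        If False, :meth:`forward` returns the fused full-resolution map.
    """

    def __init__(self, in_channels_i: int, in_channels_j: int, out_channels: int,
                 *, attention: str = "learned", downscale: bool = True,
                 init_seed: int | None = None):
        super().__init__()
        if min(in_channels_i, in_channels_j, out_channels) < 1:
            raise ConfigError("channel counts must be positive")
        if attention not in ("learned", "raw"):
            raise ConfigError(f"unknown attention mode {attention!r}")
        rng = np.random.default_rng(init_seed)
        c_cat = in_channels_i + in_channels_j
        c_j = in_channels_j
        self.in_channels_i = in_channels_i
        self.in_channels_j = in_channels_j
        self.out_channels = out_channels
        self.attention_mode = attention
        self.use_downscale = downscale

        self.phi = nn.Sequential([
            nn.Conv2d(c_cat, c_j, 3, padding=1, rng=rng),
            nn.BatchNorm2d(c_j),
            nn.ReLU(),
            nn.Conv2d(c_j, c_j, 3, padding=1, rng=rng),
            nn.BatchNorm2d(c_j),
            nn.Conv2d(c_j, c_j, 1, rng=rng),
        ])
        # zero init => D = 0 => neutral gate att = 0.5 at the start of training
        self.att_conv = nn.Conv2d(c_cat, c_j, 1, zero_init=True)
        self.down_main = nn.Sequential([
            nn.Conv2d(c_j, out_channels, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(out_channels),
        ])
        self.down_short = nn.Sequential([
            nn.Conv2d(c_j, out_channels, 1, stride=2, rng=rng),
            nn.BatchNorm2d(out_channels),
        ])

    # -- sub-operations ------------------------------------------------
    def attention_map(self, concat) -> Tensor:
        cat = _as_batch(concat)
        expected = self.in_channels_i + self.in_channels_j
        if cat.shape[1] != expected:
            raise ShapeError(
                f"concat has {cat.shape[1]} channels, block expects {expected}")
        if self.attention_mode == "learned":
            d = self.att_conv(cat)
        else:
            d = _slice_channels(cat, self.in_channels_i, expected)
        return nn.sigmoid(d)

    def residual_branch(self, concat, f_j) -> Tensor:
        cat, fj = _as_batch(concat), _as_batch(f_j)
        return self.phi(cat) + fj

    def fuse(self, f_i, f_j) -> Tensor:
        """(1 + Att) * (Phi(concat) + F_j), at the input resolution."""
        fi, fj = _as_batch(f_i), _as_batch(f_j)
        if fi.shape[1] != self.in_channels_i or fj.shape[1] != self.in_channels_j:
            raise ShapeError(
                f"inputs have channels ({fi.shape[1]}, {fj.shape[1]}); block is "
                f"configured for ({self.in_channels_i}, {self.in_channels_j})")
        cat = concat_maps(fi, fj)
        att = self.attention_map(cat)
        r = self.residual_branch(cat, fj)
        return (1.0 + att) * r

    def downscale_map(self, fused) -> Tensor:
        f = _as_batch(fused)
        if f.shape[2] % 2:
            raise InvalidInputError(
                f"stride-2 downscale needs an even side, got {f.shape[2]}")
        return nn.relu(self.down_main(f) + self.down_short(f))

    def forward(self, f_i, f_j) -> Tensor:
        fused = self.fuse(f_i, f_j)
        return self.downscale_map(fused) if self.use_downscale else fused


def _slice_channels(x: Tensor, lo: int, hi: int) -> Tensor:
    data = x.data[:, lo:hi]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, lo:hi] = g
        return (gx,)

    out = Tensor(data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


# -- functional wrappers (module-level operation surface) --------------

def attention_map(block: ARMBlock, concat) -> Tensor:
    return block.attention_map(concat)


def residual_branch(block: ARMBlock, concat, f_j) -> Tensor:
    return block.residual_branch(concat, f_j)


def arm_fuse(block: ARMBlock, f_i, f_j) -> Tensor:
    return block.fuse(f_i, f_j)


def arm_downscale(block: ARMBlock, fused) -> Tensor:
    return block.downscale_map(fused)


def arm_forward(block: ARMBlock, f_i, f_j) -> Tensor:
    return block.downscale_map(block.fuse(f_i, f_j))
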