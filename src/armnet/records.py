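"""Labeled image records and split specifications.

An :class:`ImageRecord` is one labeled face image: an H x W x 3 uint8
pixel grid, the individual's class label, a stable source identifier,
and a provenance tag distinguishing original frames from offline
augmentation products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

AUG_OPS = ("mirror", "pan", "brightness", "blur")


@dataclass
class ImageRecord:
    pixels: np.ndarray
    label: str
    source_id: str
    provenance: str = "original"
    aug_op: str | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 9 or px.shape[1] < 9:
            raise InvalidInputError(
                f"image too small to hash: {px.shape[0]}x{px.shape[1]} (need >= 9x9)")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidInputError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.provenance not in ("original", "augmented"):
            raise InvalidInputError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "augmented":
            if self.aug_op not in AUG_OPS:
                raise InvalidInputError(
                    "augmented records must carry aug_op in "
                    f"{AUG_OPS}, got {self.aug_op!r}")
        elif self.aug_op is not None:
            raise InvalidInputError("original records must not set aug_op")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus shuffling seed."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise InvalidInputError("fractions must be three non-negative reals")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidInputError(
                f"fractions must sum to 1, got {sum(self.fractions)}")
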