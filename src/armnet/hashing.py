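"""Difference-hash deduplication of near-identical frames.

Consecutive video frames of the same animal are nearly identical; the
curation step removes them with a 64-bit perceptual difference hash
(dHash): shrink to a 9-column x 8-row grayscale thumbnail, compare each
pixel with its right neighbor (8 differences per row, 64 in total), and
drop any frame whose hash lies within a Hamming distance below the
threshold (default 5) of an already kept frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .interpolate import bilinear_resize
from .records import ImageRecord

__all__ = ["PerceptualHash", "compute_dhash", "hamming_distance", "deduplicate"]

# BT.601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

HASH_BITS = 64
THUMB_COLS = 9
THUMB_ROWS = 8


@dataclass(frozen=True)
class PerceptualHash:
    """Ordered 64-bit signature; row-major 8 rows x 8 column differences."""

    bits: tuple

    def __post_init__(self):
        if len(self.bits) != HASH_BITS or any(b not in (0, 1) for b in self.bits):
            raise InvalidInputError(
                f"a perceptual hash is exactly {HASH_BITS} binary values")

    def as_int(self) -> int:
        value = 0
        for b in self.bits:
            value = (value << 1) | b
        return value

    def __str__(self):
        return f"{self.as_int():016x}"


def compute_dhash(image: ImageRecord | np.ndarray) -> PerceptualHash:
    """64-bit dHash of an image.

    Grayscale (BT.601), bilinear resize to 9x8 (columns x rows), then
    bit = 1 iff a pixel is strictly brighter than its right neighbor.
    """
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    if pixels.ndim == 3:
        gray = pixels.astype(np.float64) @ _LUMA
    elif pixels.ndim == 2:
        gray = pixels.astype(np.float64)
    else:
        raise InvalidInputError(f"expected 2-D or 3-D pixel grid, got {pixels.ndim}-D")
    if gray.shape[0] < 2 or gray.shape[1] < 2:
        raise InvalidInputError(f"degenerate image {gray.shape} cannot be hashed")
    thumb = bilinear_resize(gray, THUMB_ROWS, THUMB_COLS)
    bits = (thumb[:, :-1] > thumb[:, 1:]).astype(int)  # 8 rows x 8 diffs
    return PerceptualHash(tuple(int(b) for b in bits.ravel()))


def hamming_distance(a: PerceptualHash, b: PerceptualHash) -> int:
    """Number of differing bit positions (0..64)."""
    if len(a.bits) != len(b.bits):
        raise InvalidInputError("hash length mismatch")
    return int(sum(x != y for x, y in zip(a.bits, b.bits)))


def deduplicate(images: list[ImageRecord], threshold: int = 5
                ) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Greedy first-wins scan in input order.

    An image is removed iff its hash is at Hamming distance < ``threshold``
    from the hash of any already-kept image; the earlier image always wins.
    Returns (kept, removed).
    """
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    kept: list[ImageRecord] = []
    removed: list[ImageRecord] = []
    kept_ints: list[int] = []
    for img in images:
        h = compute_dhash(img).as_int()
        if any((h ^ k).bit_count() < threshold for k in kept_ints):
            removed.append(img)
        else:
            kept.append(img)
            kept_ints.append(h)
    return kept, removed
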