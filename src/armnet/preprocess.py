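"""Network input preparation: resize, scale, standardize.

Defaults follow the transfer-learning convention: 224x224 input with
ImageNet channel means/stds.  Both are overridable for small synthetic
experiments (e.g. 32x32 with the ``tiny`` backbone family).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError
from .interpolate import bilinear_resize
from .records import ImageRecord

__all__ = ["normalize_for_network", "IMAGENET_MEAN", "IMAGENET_STD"]

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def normalize_for_network(image: ImageRecord | np.ndarray, side: int = 224,
                          mean=IMAGENET_MEAN, std=IMAGENET_STD) -> np.ndarray:
    """Bilinear resize to side x side, scale to [0,1], standardize per channel.

    Returns a (3, side, side) float32 array in channel-first layout.
    """
    if side < 32:
        raise InvalidParameterError(f"input side must be >= 32, got {side}")
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    resized = bilinear_resize(pixels, side, side) / 255.0
    mean = np.asarray(mean, dtype=np.float64)
    std = np.asarray(std, dtype=np.float64)
    out = (resized - mean) / std
    return out.transpose(2, 0, 1).astype(np.float32)
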