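"""Plain bilinear resampling with half-pixel centers.

Used both for the 9x8 hash thumbnails and the 224x224 network input so
that one documented, testable convention covers every resize in the
pipeline (no antialiasing pre-filter; out-of-range source coordinates
clamp to the border).
"""

from __future__ import annotations

import numpy as np

__all__ = ["bilinear_resize"]


def _axis_weights(n_out: int, n_in: int):
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    lo = np.floor(src).astype(int)
    frac = src - lo
    lo_c = np.clip(lo, 0, n_in - 1)
    hi_c = np.clip(lo + 1, 0, n_in - 1)
    return lo_c, hi_c, frac


def bilinear_resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Resize an (H, W) or (H, W, C) array to (out_h, out_w[, C]) as float64."""
    img = np.asarray(image, dtype=np.float64)
    ylo, yhi, fy = _axis_weights(out_h, img.shape[0])
    xlo, xhi, fx = _axis_weights(out_w, img.shape[1])
    # interpolate rows then columns (separable); the lerp form
    # a + f*(b-a) is exact when a == b, so flat regions stay flat
    fys = fy.reshape(-1, *([1] * (img.ndim - 1)))
    rows = img[ylo] + fys * (img[yhi] - img[ylo])
    fxs = fx.reshape(1, -1, *([1] * (img.ndim - 2)))
    return rows[:, xlo] + fxs * (rows[:, xhi] - rows[:, xlo])
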