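"""Offline image augmentation: mirror, pan, brightness, blur.

The default recipe expands each original image into itself plus ten
variants (an 11x expansion): one horizontal mirror, four pans (+/-dx,
+/-dy at a fraction of the image size, edges replicated), three
multiplicative brightness changes {0.7, 1.3, 1.6} and two Gaussian
blurs (radii 1 and 2).  Augmentation is applied before training and the
products are stored, so the recipe is deterministic and label-safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import InvalidInputError, InvalidParameterError
from .records import ImageRecord

__all__ = ["AugmentRecipe", "augment_image", "augment_dataset", "DEFAULT_RECIPE"]


@dataclass(frozen=True)
class AugmentRecipe:
    """Parameter set for the offline expansion (default: 11x)."""

    pan_fraction: float = 0.1
    brightness_factors: tuple = (0.7, 1.3, 1.6)
    blur_radii: tuple = (1.0, 2.0)

    def variants(self, height: int, width: int) -> list[tuple[str, dict]]:
        dx = max(1, round(self.pan_fraction * width))
        dy = max(1, round(self.pan_fraction * height))
        ops: list[tuple[str, dict]] = [("mirror", {})]
        ops += [("pan", {"dx": d, "dy": 0}) for d in (dx, -dx)]
        ops += [("pan", {"dx": 0, "dy": d}) for d in (dy, -dy)]
        ops += [("brightness", {"factor": f}) for f in self.brightness_factors]
        ops += [("blur", {"radius": r}) for r in self.blur_radii]
        return ops


DEFAULT_RECIPE = AugmentRecipe()


def _mirror(px: np.ndarray) -> np.ndarray:
    return px[:, ::-1].copy()


def _pan(px: np.ndarray, dx: int, dy: int) -> np.ndarray:
    h, w = px.shape[:2]
    if abs(dx) >= w or abs(dy) >= h:
        raise InvalidParameterError(
            f"pan displacement ({dx},{dy}) >= image size ({w},{h})")
    padded = np.pad(px, ((abs(dy),) * 2, (abs(dx),) * 2, (0, 0)), mode="edge")
    # positive dx moves content to the right, positive dy moves it down
    y0 = abs(dy) - dy
    x0 = abs(dx) - dx
    return padded[y0:y0 + h, x0:x0 + w].copy()


def _brightness(px: np.ndarray, factor: float) -> np.ndarray:
    if factor < 0:
        raise InvalidParameterError("brightness factor must be non-negative")
    return np.clip(np.rint(px.astype(np.float64) * factor), 0, 255).astype(np.uint8)


def _blur(px: np.ndarray, radius: float) -> np.ndarray:
    if radius <= 0:
        raise InvalidParameterError("blur radius must be positive")
    out = gaussian_filter(px.astype(np.float64), sigma=(radius, radius, 0),
                          mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_image(image: ImageRecord, op: str, **params) -> ImageRecord:
    """Apply one augmentation to an original record; label preserved."""
    if image.provenance != "original":
        raise InvalidInputError(
            "augmenting an already-augmented record would compound transforms")
    if op == "mirror":
        px = _mirror(image.pixels)
    elif op == "pan":
        px = _pan(image.pixels, int(params.get("dx", 0)), int(params.get("dy", 0)))
    elif op == "brightness":
        px = _brightness(image.pixels, float(params["factor"]))
    elif op == "blur":
        px = _blur(image.pixels, float(params["radius"]))
    else:
        raise InvalidParameterError(f"unknown augmentation op {op!r}")
    suffix = "_".join([op] + [f"{k}{v}" for k, v in sorted(params.items())])
    return ImageRecord(pixels=px, label=image.label,
                       source_id=f"{image.source_id}#{suffix}",
                       provenance="augmented", aug_op=op)


def augment_dataset(images: list[ImageRecord],
                    recipe: AugmentRecipe = DEFAULT_RECIPE) -> list[ImageRecord]:
    """Expand every original into itself + 10 variants (11x total)."""
    for img in images:
        if img.provenance != "original":
            raise InvalidInputError(
                f"record {img.source_id!r} is already augmented; "
                "augment_dataset requires originals only")
    out: list[ImageRecord] = []
    for img in images:
        out.append(img)
        for op, params in recipe.variants(img.height, img.width):
            out.append(augment_image(img, op, **params))
    return out
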