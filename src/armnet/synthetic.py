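"""Procedural face-like image generation for pipeline testing.

Real enrollment data for individual-animal recognition cannot be
bundled, so this module draws labeled "faces" with the statistical
structure the pipeline assumes: each class is a distinct procedural
face (elliptical head, two eye blobs, a muzzle patch, class-specific
geometry and base color on a class-specific background gradient), and
each image of a class is a small random perturbation of that face
(rotation, translation, brightness jitter, additive noise).  A second
generator emits "video bursts": runs of near-duplicate frames whose
hashes stay within the deduplication threshold by construction — the
redundancy the curation step must remove.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, rotate, shift

from .exceptions import ArmnetError, InvalidInputError, InvalidParameterError
from .hashing import compute_dhash, hamming_distance
from .records import ImageRecord

__all__ = ["SynthSpec", "generate_dataset", "generate_burst"]


@dataclass(frozen=True)
class SynthSpec:
    num_classes: int = 8
    images_per_class: int = 20
    image_side: int = 64
    burst_length: int = 0     # near-duplicate frames per base image
    jitter: float = 2.0       # additive burst noise amplitude, gray levels
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 16:
            raise InvalidParameterError("image_side must be >= 16")
        if self.num_classes < 1 or self.images_per_class < 1:
            raise InvalidInputError("counts must be >= 1")
        if self.burst_length < 0:
            raise InvalidInputError("burst_length must be >= 0")


def _class_params(spec: SynthSpec, cls: int, salt: int = 0) -> dict:
    rng = np.random.default_rng([spec.seed, cls, salt])
    hue = (cls / spec.num_classes + rng.uniform(0, 0.5 / spec.num_classes)) % 1.0
    base = np.array(colorsys.hsv_to_rgb(hue, 0.45 + 0.3 * rng.uniform(), 0.75))
    return {
        "base_color": base * 255,
        "head_rx": rng.uniform(0.28, 0.42),
        "head_ry": rng.uniform(0.32, 0.46),
        "eye_dx": rng.uniform(0.12, 0.2),
        "eye_y": rng.uniform(-0.16, -0.06),
        "eye_r": rng.uniform(0.035, 0.07),
        "muzzle_ry": rng.uniform(0.08, 0.16),
        "muzzle_y": rng.uniform(0.12, 0.24),
        "grad_angle": rng.uniform(0, 2 * np.pi),
        "grad_strength": rng.uniform(30, 80),
        "bg_level": rng.uniform(120, 200),
    }


def _draw_base_face(spec: SynthSpec, params: dict) -> np.ndarray:
    """Render one class's canonical face as float64 HxWx3."""
    s = spec.image_side
    yy, xx = np.mgrid[0:s, 0:s]
    u = (xx - s / 2) / s   # [-0.5, 0.5)
    v = (yy - s / 2) / s

    # class-specific oriented background gradient (drives hash separation)
    g = np.cos(params["grad_angle"]) * u + np.sin(params["grad_angle"]) * v
    img = np.empty((s, s, 3))
    img[:] = params["bg_level"]
    img += (g * params["grad_strength"] * 2)[:, :, None]

    head = (u / params["head_rx"]) ** 2 + (v / params["head_ry"]) ** 2 <= 1.0
    img[head] = params["base_color"]

    for side in (-1, 1):
        eye = ((u - side * params["eye_dx"]) ** 2
               + (v - params["eye_y"]) ** 2) <= params["eye_r"] ** 2
        img[eye] = 30.0

    muzzle = ((u / (params["head_rx"] * 0.45)) ** 2
              + ((v - params["muzzle_y"]) / params["muzzle_ry"]) ** 2) <= 1.0
    img[muzzle] = params["base_color"] * 0.5 + 40.0
    return np.clip(img, 0, 255)


def _perturb(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-image pose/brightness/noise variation of a class face."""
    img = rotate(base, angle=rng.uniform(-5, 5), axes=(0, 1),
                 reshape=False, order=1, mode="nearest")
    img = shift(img, (rng.uniform(-2, 2), rng.uniform(-2, 2), 0),
                order=1, mode="nearest")
    img = img * rng.uniform(0.9, 1.1)
    img = img + rng.normal(0, 3.0, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SynthSpec) -> list[ImageRecord]:
    """K classes x N images of procedurally distinct faces."""
    records: list[ImageRecord] = []
    for cls in range(spec.num_classes):
        base = _draw_base_face(spec, _class_params(spec, cls))
        for i in range(spec.images_per_class):
            rng = np.random.default_rng([spec.seed, cls, 1000 + i])
            records.append(ImageRecord(
                pixels=_perturb(base, rng),
                label=f"individual_{cls:03d}",
                source_id=f"c{cls:03d}_img{i:04d}",
                provenance="original"))
    return records


def generate_burst(spec: SynthSpec, threshold: int = 5) -> list[ImageRecord]:
    """Near-duplicate frame runs: one base face per class plus
    ``burst_length - 1`` sub-threshold jittered copies each.

    The generator verifies its own contract: within a burst every frame
    hashes within ``threshold`` bits of its base, and every pair of
    bases is at least ``threshold`` bits apart (bases are redrawn with
    fresh class geometry if not, up to 100 attempts).
    """
    if spec.burst_length < 1:
        raise InvalidInputError("generate_burst needs burst_length >= 1")

    # Triangle-inequality calibration: every frame stays within
    # floor(t/2) bits of its base and bases are >= t + 2*floor(t/2)
    # bits apart, so pairwise within-burst distances are < t and
    # cross-burst distances >= t by construction.
    frame_budget = threshold // 2
    base_sep = threshold + 2 * frame_budget

    bases, hashes = [], []
    for cls in range(spec.num_classes):
        for salt in range(100):
            base = np.clip(np.rint(_draw_base_face(
                spec, _class_params(spec, cls, salt))), 0, 255).astype(np.uint8)
            h = compute_dhash(base)
            if all(hamming_distance(h, other) >= base_sep for other in hashes):
                bases.append(base)
                hashes.append(h)
                break
        else:
            raise ArmnetError(
                f"could not draw a base face for class {cls} at hash "
                f"distance >= {base_sep} from earlier bases in 100 attempts")

    frames: list[list[ImageRecord]] = []
    for cls, (base, base_hash) in enumerate(zip(bases, hashes)):
        label = f"individual_{cls:03d}"
        burst = [ImageRecord(pixels=base, label=label,
                             source_id=f"c{cls:03d}_frame0000")]
        for frame in range(1, spec.burst_length):
            rng = np.random.default_rng([spec.seed, cls, 2000 + frame])
            for attempt in range(100):
                # consecutive frames differ by a slowly varying illumination
                # field, not independent pixel noise: smooth the noise so
                # local gradient ordering (hence the hash) barely moves;
                # the amplitude decays across attempts (calibration loop)
                field = gaussian_filter(
                    rng.normal(0, 1, size=base.shape[:2]),
                    sigma=spec.image_side / 8)
                amplitude = spec.jitter * 0.9 ** attempt
                field *= amplitude / (np.abs(field).max() + 1e-12)
                noisy = np.clip(np.rint(
                    base.astype(np.float64) + field[:, :, None]),
                    0, 255).astype(np.uint8)
                if hamming_distance(compute_dhash(noisy), base_hash) <= frame_budget:
                    burst.append(ImageRecord(
                        pixels=noisy, label=label,
                        source_id=f"c{cls:03d}_frame{frame:04d}"))
                    break
            else:
                raise ArmnetError(
                    f"jitter {spec.jitter} failed to stay within hash "
                    f"distance {frame_budget} after 100 attempts; lower it")
        frames.append(burst)

    # interleave in frame order (frame 0 of every burst first, then frame 1, ...)
    records: list[ImageRecord] = []
    for frame in range(spec.burst_length):
        for burst in frames:
            records.append(burst[frame])
    return records
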