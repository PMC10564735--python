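"""Stratified train/validation/test partitioning."""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .exceptions import InvalidInputError
from .records import ImageRecord, SplitSpec

__all__ = ["split_dataset"]


def _allocate(n: int, fractions) -> tuple[int, int, int]:
    """Floor-allocate per fraction; the remainder goes to train."""
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train += n - (n_train + n_val + n_test)
    return n_train, n_val, n_test


def split_dataset(images: list[ImageRecord], spec: SplitSpec = SplitSpec()
                  ) -> tuple[list[ImageRecord], list[ImageRecord], list[ImageRecord]]:
    """Disjoint, exhaustive partition; identical seed => identical result.

    With ``stratified`` the allocation is applied per class after a
    seeded shuffle within each class; otherwise to the whole list.
    """
    rng = np.random.default_rng(spec.seed)
    train: list[ImageRecord] = []
    val: list[ImageRecord] = []
    test: list[ImageRecord] = []

    if spec.stratified:
        by_class: dict[str, list[int]] = defaultdict(list)
        for i, img in enumerate(images):
            by_class[img.label].append(i)
        for label in sorted(by_class):
            idx = by_class[label]
            if not idx:
                raise InvalidInputError(f"class {label!r} has no images")
            order = rng.permutation(len(idx))
            shuffled = [images[idx[k]] for k in order]
            n_tr, n_va, _ = _allocate(len(shuffled), spec.fractions)
            train += shuffled[:n_tr]
            val += shuffled[n_tr:n_tr + n_va]
            test += shuffled[n_tr + n_va:]
    else:
        order = rng.permutation(len(images))
        shuffled = [images[k] for k in order]
        n_tr, n_va, _ = _allocate(len(shuffled), spec.fractions)
        train = shuffled[:n_tr]
        val = shuffled[n_tr:n_tr + n_va]
        test = shuffled[n_tr + n_va:]
    return train, val, test
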