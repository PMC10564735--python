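"""Dataset I/O: one-folder-per-class image trees and CSV manifests."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import InvalidInputError
from .records import ImageRecord

__all__ = ["load_image_tree", "load_manifest", "write_image_tree",
           "write_manifest"]

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def load_image_tree(root) -> list[ImageRecord]:
    """Read ``root/<class_name>/*.{png,jpg,jpeg}`` into records."""
    root = Path(root)
    if not root.is_dir():
        raise InvalidInputError(f"{root} is not a directory")
    records = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in IMAGE_EXTS:
                continue
            pixels = np.asarray(Image.open(path).convert("RGB"))
            records.append(ImageRecord(pixels=pixels, label=class_dir.name,
                                       source_id=str(path.relative_to(root))))
    if not records:
        raise InvalidInputError(f"no images found under {root}")
    return records


def load_manifest(path, image_root=None) -> list[ImageRecord]:
    """Read a ``path,label`` CSV manifest (paths relative to image_root)."""
    path = Path(path)
    base = Path(image_root) if image_root else path.parent
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise InvalidInputError("manifest needs a header with path,label")
        for row in reader:
            img_path = base / row["path"]
            pixels = np.asarray(Image.open(img_path).convert("RGB"))
            records.append(ImageRecord(
                pixels=pixels, label=row["label"], source_id=row["path"],
                provenance=row.get("provenance") or "original",
                aug_op=row.get("aug_op") or None))
    return records


def _safe_name(source_id: str) -> str:
    stem = source_id.replace("/", "_").replace("\\", "_").replace("#", "_")
    return stem if stem.lower().endswith(IMAGE_EXTS) else stem + ".png"


def write_image_tree(records, root) -> list[tuple[str, ImageRecord]]:
    """Write records into a class-per-folder tree; returns (relpath, record)."""
    root = Path(root)
    written = []
    for rec in records:
        class_dir = root / rec.label
        class_dir.mkdir(parents=True, exist_ok=True)
        rel = f"{rec.label}/{_safe_name(rec.source_id)}"
        Image.fromarray(rec.pixels).save(root / rel)
        written.append((rel, rec))
    return written


def write_manifest(entries, path, split_of=None) -> None:
    """CSV manifest with path,label,split,provenance,aug_op columns.

    ``entries`` are (relpath, record) pairs; ``split_of`` optionally
    maps a record's source_id to its split name.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split", "provenance", "aug_op"])
        for rel, rec in entries:
            split = split_of.get(rec.source_id, "") if split_of else ""
            writer.writerow([rel, rec.label, split, rec.provenance,
                             rec.aug_op or ""])
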