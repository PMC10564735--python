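"""Training loop, k-fold protocol, evaluation, cost and visualization.

The training protocol mirrors the study conditions: Adam with learning
rate 1e-4 (1e-5 in the 5-fold variant), batch size 16, cross-entropy
loss, a fixed epoch budget, and a best-validation-accuracy checkpoint
kept alongside the final weights.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .exceptions import InvalidInputError
from .metrics import CostMeasure, EvalReport, compute_metrics
from .preprocess import normalize_for_network

__all__ = [
    "TrainConfig", "TrainResult", "train", "kfold_train", "evaluate",
    "predict", "count_params", "measure_cost", "export_feature_maps",
    "records_to_arrays", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    folds: int | None = None          # k-fold preset: folds=5, lr=1e-5
    target_train_acc: float | None = None  # optional early exit for harnesses

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidInputError("epochs/batch_size/learning_rate out of range")
        if self.optimizer != "adam":
            raise InvalidInputError(f"unsupported optimizer {self.optimizer!r}")
        if self.folds is not None and self.folds < 2:
            raise InvalidInputError("folds must be >= 2 when present")


@dataclass
class TrainResult:
    model: nn.Module
    trace: list          # dicts: epoch, loss, train_acc, val_acc
    best_val_acc: float
    best_state: dict     # state_dict at the best validation epoch

    def trace_rows(self):
        return [(r["epoch"], r["loss"], r["train_acc"], r["val_acc"])
                for r in self.trace]


def records_to_arrays(records, side: int, class_names=None,
                      mean=None, std=None):
    """Stack ImageRecords into (X, y) network arrays.

    Returns (X float32 (N,3,side,side), y int labels, class_names).
    """
    if not records:
        raise InvalidInputError("empty record list")
    if class_names is None:
        class_names = sorted({r.label for r in records})
    index = {c: i for i, c in enumerate(class_names)}
    unknown = {r.label for r in records} - set(index)
    if unknown:
        raise InvalidInputError(f"labels not in the class set: {sorted(unknown)}")
    kwargs = {}
    if mean is not None:
        kwargs["mean"] = mean
    if std is not None:
        kwargs["std"] = std
    x = np.stack([normalize_for_network(r, side=side, **kwargs) for r in records])
    y = np.array([index[r.label] for r in records], dtype=np.int64)
    return x, y, list(class_names)


def predict(model: nn.Module, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Class predictions for a stacked input array."""
    model.eval()
    out = []
    for start in range(0, len(x), batch_size):
        logits = model(x[start:start + batch_size])
        out.append(logits.data.argmax(axis=1))
    return np.concatenate(out)


def _check_labels(y, num_classes, what):
    y = np.asarray(y)
    if y.size == 0:
        raise InvalidInputError(f"{what} split is empty")
    if len(np.unique(y)) < 2 and what == "train":
        raise InvalidInputError("training requires at least 2 classes")
    if y.min() < 0 or y.max() >= num_classes:
        raise InvalidInputError(f"{what} labels exceed the model's class count")
    return y


def train(model: nn.Module, train_set, val_set, config: TrainConfig) -> TrainResult:
    """Adam / cross-entropy training with a per-epoch accuracy trace.

    ``train_set``/``val_set`` are (X, y) pairs of stacked arrays.  The
    state dict of the best validation epoch is retained.  Fully
    deterministic for a fixed config seed and model init seed.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    num_classes = model.head.weight.shape[0]
    y_tr = _check_labels(y_tr, num_classes, "train")
    y_va = _check_labels(y_va, num_classes, "val")

    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trace = []
    best_val, best_state = -1.0, model.state_dict()
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(len(x_tr))
        losses, correct = [], 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            logits = model(x_tr[idx])
            loss = nn.cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_tr[idx]).sum())
        train_acc = 100.0 * correct / len(order)
        val_acc = 100.0 * float(np.mean(predict(model, x_va) == y_va))
        trace.append({"epoch": epoch, "loss": float(np.mean(losses)),
                      "train_acc": train_acc, "val_acc": val_acc})
        if val_acc > best_val:
            best_val = val_acc
            best_state = copy.deepcopy(model.state_dict())
        if (config.target_train_acc is not None
                and train_acc >= config.target_train_acc):
            break
    return TrainResult(model=model, trace=trace, best_val_acc=best_val,
                       best_state=best_state)


def kfold_train(model_factory, dataset, config: TrainConfig):
    """Stratified k-fold protocol: fresh model per fold, held-out eval.

    ``model_factory(fold_index)`` must return an untrained model;
    ``dataset`` is an (X, y) pair.  Returns (per-fold EvalReports, mean
    macro-F1 across folds).
    """
    x, y = dataset
    folds = config.folds or 5
    labels, counts = np.unique(np.asarray(y), return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < folds:
            raise InvalidInputError(
                f"class {lab} has {cnt} items, fewer than {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    reports = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(x, y)):
        model = model_factory(fold)
        train(model, (x[tr_idx], y[tr_idx]), (x[te_idx], y[te_idx]), config)
        num_classes = model.head.weight.shape[0]
        reports.append(evaluate(model, (x[te_idx], y[te_idx]),
                                [str(c) for c in range(num_classes)]))
    mean_macro_f1 = float(np.mean([r.macro_f1 for r in reports]))
    return reports, mean_macro_f1


def evaluate(model: nn.Module, test_set, class_names) -> EvalReport:
    """Confusion-based per-class and macro precision/recall/F1."""
    x, y = test_set
    y = _check_labels(y, len(class_names), "test")
    return compute_metrics(y, predict(model, x), class_names)


def count_params(model: nn.Module) -> int:
    """Total trainable parameter count."""
    return model.num_params()


def measure_cost(model: nn.Module, images: np.ndarray, repeats: int = 1,
                 warmup: int = 10) -> CostMeasure:
    """Wall-clock seconds per single-image prediction (Tn / n).

    Hardware-dependent; reported, never asserted against reference
    figures.  Warm-up predictions are excluded from Tn.
    """
    if len(images) < 1:
        raise InvalidInputError("need at least one image")
    model.eval()
    for _ in range(warmup):
        model(images[:1])
    t0 = time.perf_counter()
    n = 0
    for _ in range(repeats):
        for i in range(len(images)):
            model(images[i:i + 1])
            n += 1
    tn = time.perf_counter() - t0
    return CostMeasure(total_time=tn, n=n, cost=tn / n)


def heatmap_from_activation(act: np.ndarray) -> np.ndarray:
    """Channel-mean activation min-max normalized to uint8 [0, 255]."""
    act = np.asarray(act)
    if act.ndim == 4:
        act = act[0]
    mean = act.mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi - lo < 1e-12:
        return np.zeros_like(mean, dtype=np.uint8)
    return np.rint(255.0 * (mean - lo) / (hi - lo)).astype(np.uint8)


def export_feature_maps(model: nn.Module, image: np.ndarray, layer_names,
                        out_dir) -> list:
    """Render named captured activations as grayscale heat-map PNGs."""
    from PIL import Image

    model.eval()
    model(image[None] if image.ndim == 3 else image, capture=True)
    available = sorted(model.activations)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in layer_names:
        if name not in model.activations:
            raise InvalidInputError(
                f"unknown layer {name!r}; available: {available}")
        heat = heatmap_from_activation(model.activations[name])
        path = out_dir / f"{name}.png"
        Image.fromarray(heat, mode="L").save(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: nn.Module, path, manifest: dict | None = None) -> None:
    """Weights as .npz next to a JSON manifest (round-trip loadable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if manifest is None and hasattr(model, "build_manifest"):
        manifest = model.build_manifest()
    if manifest is not None:
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(model: nn.Module, path) -> nn.Module:
    with np.load(Path(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
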