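"""Training recipe and evaluation metrics.

The recipe is fixed-step Adam on softmax cross-entropy, with the learning
rate decayed by a constant factor every ``decay_every`` epochs:
``lr(e) = initial_lr / decay_factor ** floor(e / decay_every)`` (defaults
0.001 decayed x10 every 50 epochs, 200 epochs). The retained checkpoint is
the epoch with the best validation accuracy (ties break to the earliest
epoch).

Evaluation reduces a K-class confusion matrix one-vs-rest per class:

    accuracy    = trace / total
    sensitivity = TP / (TP + FN)          (per class, macro-averaged)
    specificity = TN / (TN + FP)          (per class, macro-averaged)

Macro averaging weights every class equally, which is the natural choice
for an imbalanced standard-plane dataset; classes with no true samples
have undefined sensitivity and are excluded from the macro mean (and
flagged in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from . import nn
from .architectures import ArchSpec, instantiate

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "MetricsReport",
    "lr_at",
    "train",
    "predict",
    "evaluate",
    "confusion",
    "binary_counts",
    "metrics",
    "load_images",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    initial_lr: float = 0.001
    decay_factor: float = 10.0
    decay_every: int = 50
    batch_size: int = 32
    input_size: tuple = (224, 288)  # (H, W)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.decay_every < 1:
            raise ValueError("epochs and decay_every must be >= 1")
        if self.initial_lr <= 0 or self.decay_factor < 1:
            raise ValueError("need initial_lr > 0 and decay_factor >= 1")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant learning rate at a 0-based epoch."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.initial_lr / cfg.decay_factor ** (epoch // cfg.decay_every)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # dicts per epoch
    best_epoch: int = -1
    best_val_accuracy: float = -1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


# ---------------------------------------------------------------------------
# data loading

def load_images(manifest: pd.DataFrame, input_size: tuple,
                categories: tuple) -> tuple:
    """Load, resize, and per-image standardize the manifest's images.

    Returns ``(x, y)`` with ``x`` of shape (N, 1, H, W) float32 (zero mean,
    unit variance per image) and integer labels ``y`` indexing
    ``categories``.
    """
    cat_index = {c: i for i, c in enumerate(categories)}
    xs, ys = [], []
    for _, rec in manifest.iterrows():
        if rec["category"] not in cat_index:
            raise ValueError(f"category {rec['category']!r} not in scheme "
                             f"{list(categories)}")
        img = np.asarray(Image.open(rec["path"]).convert("L"),
                         dtype=np.float64) / 255.0
        if img.shape != tuple(input_size):
            img = resize(img, input_size, anti_aliasing=True)
        xs.append(_standardize(img))
        ys.append(cat_index[rec["category"]])
    x = np.stack(xs).astype(np.float32)[:, None]
    return x, np.asarray(ys, dtype=np.int64)


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    return (img - img.mean()) / (sd if sd > 1e-8 else 1.0)


# ---------------------------------------------------------------------------
# training loop

def train(spec: ArchSpec, train_manifest: pd.DataFrame,
          val_manifest: pd.DataFrame, cfg: TrainConfig,
          categories: tuple, data: tuple | None = None):
    """Train a network from a spec; returns ``(model, history)``.

    ``data`` may supply preloaded ``((x_tr, y_tr), (x_val, y_val))`` arrays
    to skip image I/O (arrays must already be standardized); otherwise the
    manifests' images are loaded at ``cfg.input_size``. The model returned
    carries the best-validation-accuracy parameters. Deterministic given
    ``cfg.seed`` up to floating-point non-associativity.
    """
    if data is not None:
        (x_tr, y_tr), (x_val, y_val) = data
    else:
        if len(train_manifest) == 0 or len(val_manifest) == 0:
            raise ValueError("train and val manifests must be nonempty")
        x_tr, y_tr = load_images(train_manifest, cfg.input_size, categories)
        x_val, y_val = load_images(val_manifest, cfg.input_size, categories)
    if len(x_tr) == 0 or len(x_val) == 0:
        raise ValueError("train and val sets must be nonempty")
    if len(categories) != spec.num_classes:
        raise ValueError("category scheme size does not match the network")

    model = instantiate(spec, seed=cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    best_state = None

    for epoch in range(cfg.epochs):
        opt.lr = lr_at(epoch, cfg)
        order = rng.permutation(len(x_tr))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = model.forward(x_tr[sel], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_tr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(sel))
            correct += int((_argmax(logits) == y_tr[sel]).sum())
        train_loss = float(np.sum(losses) / len(order))
        train_acc = correct / len(order)
        val_loss, val_acc = _evaluate_loss_acc(model, x_val, y_val,
                                               cfg.batch_size)
        history.epochs.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss": train_loss, "train_acc": train_acc,
            "val_loss": val_loss, "val_acc": val_acc,
        })
        if val_acc > history.best_val_accuracy:
            history.best_val_accuracy = val_acc
            history.best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return model, history


def _argmax(logits: np.ndarray) -> np.ndarray:
    # np.argmax takes the lowest index on ties, the pinned tie-break
    return np.argmax(logits, axis=1)


def _evaluate_loss_acc(model, x, y, batch_size):
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[start:start + batch_size])
        losses.append(loss * len(logits))
        correct += int((_argmax(logits) == y[start:start + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict(model, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Argmax class predictions in inference mode."""
    out = []
    for start in range(0, len(x), batch_size):
        out.append(_argmax(model.forward(x[start:start + batch_size],
                                         train=False)))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def evaluate(model, manifest: pd.DataFrame, cfg: TrainConfig,
             categories: tuple, data: tuple | None = None):
    """Confusion matrix and metrics of a model on a manifest's images."""
    if data is not None:
        x, y = data
    else:
        x, y = load_images(manifest, cfg.input_size, categories)
    pred = predict(model, x, cfg.batch_size)
    cm = confusion(y, pred, len(categories))
    return cm, metrics(cm)


# ---------------------------------------------------------------------------
# metrics

def confusion(true_labels, predicted_labels, num_classes: int) -> np.ndarray:
    """K x K count matrix; rows are true classes, columns predictions."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label lists must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def binary_counts(cm: np.ndarray, c: int) -> dict:
    """One-vs-rest TP/FP/TN/FN for class ``c``."""
    cm = np.asarray(cm)
    if not 0 <= c < cm.shape[0]:
        raise ValueError(f"class {c} outside [0, {cm.shape[0]})")
    total = int(cm.sum())
    tp = int(cm[c, c])
    fn = int(cm[c].sum()) - tp
    fp = int(cm[:, c].sum()) - tp
    return {"TP": tp, "FP": fp, "FN": fn, "TN": total - tp - fn - fp}


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float       # macro mean over defined classes
    specificity: float       # macro mean
    per_class: list          # (class index, sensitivity or None, specificity)
    undefined_sensitivity: list  # classes with no true samples


def metrics(cm: np.ndarray) -> MetricsReport:
    """Accuracy / macro sensitivity / macro specificity from a confusion
    matrix."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = float(np.trace(cm)) / total
    per_class, sens, spec, undefined = [], [], [], []
    for c in range(cm.shape[0]):
        b = binary_counts(cm, c)
        sp = b["TN"] / (b["TN"] + b["FP"]) if b["TN"] + b["FP"] else 1.0
        if b["TP"] + b["FN"] == 0:
            per_class.append((c, None, sp))
            undefined.append(c)
        else:
            sn = b["TP"] / (b["TP"] + b["FN"])
            per_class.append((c, sn, sp))
            sens.append(sn)
        spec.append(sp)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=float(np.mean(sens)) if sens else float("nan"),
        specificity=float(np.mean(spec)),
        per_class=per_class,
        undefined_sensitivity=undefined,
    )


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model, path, spec: ArchSpec | None = None) -> None:
    """Write parameters (and optionally the arch spec) as an .npz file."""
    state = model.state_dict()
    if spec is None:
        spec = model.spec
    np.savez(path, __spec__=np.frombuffer(
        spec.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path, seed: int = 0):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        spec = ArchSpec.from_json(bytes(data["__spec__"]).decode())
        state = {k: data[k] for k in data.files if k != "__spec__"}
    model = instantiate(spec, seed=seed)
    model.load_state_dict(state)
    return model
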