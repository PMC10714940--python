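"""Training recipe and evaluation metrics for the water-stress classifier.

Training follows the study recipe: categorical cross-entropy on softmax
probabilities, He initialization with zero biases, the Adam optimizer at
learning rate 1e-4, batch size 16, geometric augmentation (90° rotations,
horizontal/vertical flips applied identically to every frame of a
sequence), a stratified 4:1 train/validation split, and best-validation
checkpoint selection.  Evaluation reports the confusion matrix, one-vs-rest
per-class accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall
TP/(TP+FN), F1, and their macro averages.
"""

from __future__ import annotations

import contextlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._autodiff import Tensor, clip_min
from .model_core import StressNet
from .roi_sequences import (CLASS_NAMES, ImageSequence, InvalidArgumentError,
                            MultispectralFrame, channel_stats, _apply_stats,
                            logger)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the study recipe)."""
    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 100
    train_fraction: float = 0.8          # the 4:1 train/validation split
    seed: int = 0
    rotate90: bool = True
    hflip: bool = True
    vflip: bool = True
    normalization: str = "minmax"

    def __post_init__(self):
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise InvalidArgumentError("train fraction must be in (0, 1)")
        if self.epochs < 0:
            raise InvalidArgumentError("epochs must be >= 0")


def parse_split_ratio(ratio) -> float:
    """Accept a fraction (0.8) or a 'train:val' string ('4:1')."""
    if isinstance(ratio, str):
        a, b = (float(x) for x in ratio.split(":"))
        if b <= 0 or a <= 0:
            raise InvalidArgumentError(f"invalid split ratio {ratio!r}")
        return a / (a + b)
    f = float(ratio)
    if not 0 < f < 1:
        raise InvalidArgumentError(f"train fraction must be in (0,1), got {f}")
    return f


# ---------------------------------------------------------------------------
# loss and initialization
# ---------------------------------------------------------------------------

def cross_entropy(y_true_onehot, y_pred_probs, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy −Σ_i y_i log(ŷ_i) over the batch.

    Predictions are clamped at eps before the log.  Zero for a perfect
    prediction, ln K for a uniform one.
    """
    y = np.atleast_2d(np.asarray(y_true_onehot, dtype=np.float64))
    p = np.atleast_2d(np.asarray(y_pred_probs, dtype=np.float64))
    if y.shape != p.shape:
        raise InvalidArgumentError(f"shape mismatch {y.shape} vs {p.shape}")
    return float(-(y * np.log(np.maximum(p, eps))).sum(axis=1).mean())


def _cross_entropy_tensor(probs: Tensor, onehot: np.ndarray,
                          eps: float = 1e-12) -> Tensor:
    b = probs.shape[0]
    return -(Tensor(onehot) * clip_min(probs, eps).log()).sum() / float(b)


def one_hot(labels, n_classes: int = 3) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def he_init(shapes: list, seed: int = 0) -> list:
    """He-initialized arrays: weights ~ N(0, 2/fan_in), biases exactly zero.

    Fan-in rule: 1-D shapes are biases (zeros); 2-D (fan_in, fan_out)
    matrices use shape[0]; 4-D convolution kernels (out, in, kh, kw) use
    in·kh·kw.
    """
    rng = np.random.default_rng(seed)
    out = []
    for shape in shapes:
        shape = tuple(shape)
        if len(shape) == 1:
            out.append(np.zeros(shape))
        else:
            fan_in = shape[0] if len(shape) == 2 else int(np.prod(shape[1:]))
            out.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape))
    return out


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transform_array(arr: np.ndarray, k_rot: int, hflip: bool, vflip: bool):
    out = arr
    if k_rot:
        out = np.rot90(out, k=k_rot, axes=(-2, -1))
    if hflip:
        out = out[..., :, ::-1]
    if vflip:
        out = out[..., ::-1, :]
    return np.ascontiguousarray(out)


def sample_transform(rng: np.random.Generator, rotate90=True, hflip=True,
                     vflip=True) -> tuple:
    """One geometric transform tuple (rotation quarter-turns, flips)."""
    return (int(rng.integers(0, 4)) if rotate90 else 0,
            bool(rng.integers(0, 2)) if hflip else False,
            bool(rng.integers(0, 2)) if vflip else False)


def augment(seq, flags: dict | None = None, seed: int = 0,
            transform: tuple | None = None):
    """Apply one random geometric transform to every frame of a sequence.

    A single (rotation, hflip, vflip) tuple is drawn per sequence and applied
    identically to every frame and channel, preserving temporal coherence;
    the label is unchanged.  Accepts an ImageSequence or a (T,C,H,W) array.
    """
    flags = flags or {}
    arr = seq.as_array() if isinstance(seq, ImageSequence) else np.asarray(seq)
    if transform is None:
        transform = sample_transform(np.random.default_rng(seed),
                                     flags.get("rotate90", True),
                                     flags.get("hflip", True),
                                     flags.get("vflip", True))
    k_rot, hf, vf = transform
    if k_rot % 2 and arr.shape[-1] != arr.shape[-2]:
        raise InvalidArgumentError("90-degree rotation requires square frames")
    out = _transform_array(arr, k_rot, hf, vf)
    if isinstance(seq, ImageSequence):
        frames = [MultispectralFrame(out[t], f.channel_names, f.date_index,
                                     f.plot_id)
                  for t, f in enumerate(seq.frames)]
        return ImageSequence(frames, seq.label, seq.sequence_id)
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(archive: dict, ratio=0.8, seed: int = 0) -> tuple:
    """Stratified train/validation split of a sequence archive.

    Per class, round-half-up(n · fraction) sequences go to training and the
    remainder to validation; the partition is disjoint and deterministic for
    a given seed.
    """
    frac = parse_split_ratio(ratio)
    labels = np.asarray(archive["labels"])
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise InvalidArgumentError(
                f"class {cls} has {idx.size} sequence(s); need >= 2 to stratify")
        n_train = int(np.floor(idx.size * frac + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        val_idx.extend(perm[n_train:].tolist())
    train_idx, val_idx = sorted(train_idx), sorted(val_idx)

    def take(indices):
        out = dict(archive)
        out["sequences"] = archive["sequences"][indices]
        out["labels"] = labels[indices]
        if "sequence_ids" in archive:
            out["sequence_ids"] = [archive["sequence_ids"][i] for i in indices]
        out["indices"] = list(indices)
        return out

    return take(train_idx), take(val_idx)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@contextlib.contextmanager
def _inference(model: StressNet):
    """Disable gradient tracking on model parameters inside the block."""
    params = model.parameters()
    for p in params:
        p.requires_grad = False
    try:
        yield
    finally:
        for p in params:
            p.requires_grad = True


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: StressNet, train_archive: dict, val_archive: dict,
          config: TrainConfig):
    """Mini-batch Adam optimization of the cross-entropy loss.

    Normalization statistics are computed on the training split only (the
    configured mode, dataset scope) and applied to both splits.  Per-epoch
    mean training loss and validation accuracy are recorded; the checkpoint
    with the best validation accuracy (ties to the earlier epoch) is
    restored into the model on return.  Fully deterministic for a given
    config seed.  Returns ``(model, history)``.
    """
    rng = np.random.default_rng(config.seed)
    stats = channel_stats(np.asarray(train_archive["sequences"], dtype=np.float64),
                          config.normalization)
    xtr = _apply_stats(np.asarray(train_archive["sequences"], dtype=np.float64), stats)
    ytr = np.asarray(train_archive["labels"], dtype=np.int64)
    xva = _apply_stats(np.asarray(val_archive["sequences"], dtype=np.float64), stats)
    yva = np.asarray(val_archive["labels"], dtype=np.int64)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = xtr.shape[0]
    history = {"train_loss": [], "val_accuracy": [], "config": asdict(config)}
    best_acc, best_epoch, best_state = -1.0, -1, model.get_state()

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = np.empty_like(xtr[idx])
            for b, i in enumerate(idx):
                tr = sample_transform(rng, config.rotate90, config.hflip,
                                      config.vflip)
                batch[b] = augment(xtr[i], transform=tr)
            probs = model.forward(batch)
            loss = _cross_entropy_tensor(probs, one_hot(ytr[idx]))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
            seen += idx.size
        val_acc = _batched_accuracy(model, xva, yva, config.batch_size)
        history["train_loss"].append(epoch_loss / max(seen, 1))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, model.get_state()
        logger.debug("epoch %d loss %.4f val_acc %.4f", epoch,
                     history["train_loss"][-1], val_acc)

    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_accuracy"] = best_acc if best_epoch >= 0 else None
    history["norm_stats"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in stats.items()}
    return model, history


def _batched_accuracy(model, x, y, batch_size) -> float:
    preds = _batched_predict(model, x, batch_size)
    return float((preds == y).mean())


def _batched_predict(model, x, batch_size=16) -> np.ndarray:
    preds = []
    with _inference(model):
        for start in range(0, x.shape[0], batch_size):
            preds.append(model.predict(x[start:start + batch_size]))
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """K×K confusion matrix (rows = true class) and one-vs-rest counts."""
    matrix: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = 3):
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        m = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(m, (y_true, y_pred), 1)
        tp = np.diag(m).astype(np.int64)
        fp = m.sum(axis=0) - tp
        fn = m.sum(axis=1) - tp
        tn = m.sum() - tp - fp - fn
        return cls(m, tp, fp, fn, tn)


def _safe_div(a, b):
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    return np.divide(a, b, out=np.zeros_like(a), where=b != 0)


def metrics_from_counts(tp, fp, fn, tn) -> dict:
    """Per-class accuracy/precision/recall/F1 from one-vs-rest counts:
    Acc=(TP+TN)/(TP+TN+FP+FN), Pre=TP/(TP+FP), Rec=TP/(TP+FN)."""
    tp, fp, fn, tn = (np.asarray(v, dtype=np.float64) for v in (tp, fp, fn, tn))
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "f1": _safe_div(2 * precision * recall, precision + recall),
    }


@dataclass
class MetricsReport:
    """Evaluation summary: overall and per-class metrics, macro averages."""
    counts: ConfusionCounts
    accuracy: float
    per_class: dict                       # name -> array over classes
    macro_precision: float
    macro_recall: float
    macro_f1: float
    supports: np.ndarray
    class_names: tuple = tuple(CLASS_NAMES)
    history: dict | None = None

    def accuracy_table(self) -> pd.DataFrame:
        """Class-level one-vs-rest accuracy (class name, label, score)."""
        return pd.DataFrame({
            "Class Name": list(self.class_names),
            "Class Label": np.arange(len(self.class_names)),
            "Accuracy Score": self.per_class["accuracy"],
        })

    def classification_report(self) -> pd.DataFrame:
        """Per-class precision/recall/F1/support."""
        return pd.DataFrame({
            "Class": np.arange(len(self.class_names)),
            "Precision": self.per_class["precision"],
            "Recall": self.per_class["recall"],
            "F1-Score": self.per_class["f1"],
            "Support": self.supports,
        })


def report_from_predictions(y_true, y_pred, n_classes: int = 3) -> MetricsReport:
    counts = ConfusionCounts.from_predictions(y_true, y_pred, n_classes)
    per_class = metrics_from_counts(counts.tp, counts.fp, counts.fn, counts.tn)
    supports = counts.matrix.sum(axis=1)
    return MetricsReport(
        counts=counts,
        accuracy=float(np.trace(counts.matrix) / max(counts.matrix.sum(), 1)),
        per_class=per_class,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        supports=supports,
    )


def evaluate(model: StressNet, archive: dict, stats: dict | None = None,
             batch_size: int = 16) -> MetricsReport:
    """Argmax predictions on an archive, summarized as a MetricsReport.

    Pass the training-split normalization statistics through ``stats`` so
    evaluation sees data on the training scale.
    """
    x = np.asarray(archive["sequences"], dtype=np.float64)
    if x.shape[0] == 0:
        raise InvalidArgumentError("dataset is empty")
    if stats is not None:
        x = _apply_stats(x, _stats_from_history(stats))
    preds = _batched_predict(model, x, batch_size)
    return report_from_predictions(archive["labels"], preds)


def _stats_from_history(stats: dict) -> dict:
    return {k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in stats.items()}
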