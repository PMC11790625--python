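"""Full-batch training loop, metrics, and checkpointing.

Training is plain full-graph gradient descent: forward pass over the
whole graph every epoch, cross-entropy on train-mask nodes, Adam
update, validation loss/accuracy on the val mask.  No early stopping,
no neighbor sampling — the graphs this tool builds are desk-scale.
"""

from __future__ import annotations

import pickle
import resource
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from ..graph_build import LearningGraph
from ._autodiff import Adam, Tensor, no_grad
from .models import TrainConfig, init_model

__all__ = [
    "TrainingHistory",
    "Metrics",
    "train",
    "evaluate",
    "predict",
    "confusion_matrix",
    "cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    peak_memory_mb: float = 0.0  # informational only


@dataclass
class Metrics:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: np.ndarray
    label_names: list[str]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                name: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                }
                for i, name in enumerate(self.label_names)
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "confusion_matrix": self.confusion.tolist(),
        }


def cross_entropy(logits: Tensor, labels: np.ndarray, idx: np.ndarray) -> Tensor:
    """Mean cross-entropy over the nodes in ``idx``."""
    logp = logits.log_softmax()
    sel = logp.gather(idx)
    onehot = np.zeros_like(sel.value)
    onehot[np.arange(len(idx)), labels[idx]] = 1.0
    return -(sel * Tensor(onehot)).sum() * (1.0 / len(idx))


def predict(model, graph: LearningGraph) -> np.ndarray:
    """Argmax class per node from a deterministic forward pass."""
    with no_grad():
        logits = model.forward(graph.node_features, graph.edges, graph.weights)
    return logits.value.argmax(axis=1)


def train(model, graph: LearningGraph, config: TrainConfig):
    """Train in place; returns (model, TrainingHistory)."""
    config.validate()
    train_idx = np.flatnonzero(graph.train_mask)
    val_idx = np.flatnonzero(graph.val_mask)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and val masks must be nonempty")
    opt = Adam(model.params, lr=config.learning_rate)
    dropout_rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        logits = model.forward(
            graph.node_features, graph.edges, graph.weights,
            training=True, rng=dropout_rng,
        )
        loss = cross_entropy(logits, graph.labels, train_idx)
        if not np.isfinite(loss.value):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}: {loss.value}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        train_loss_value = float(loss.value)
        del logits, loss  # free the training tape before the eval pass

        with no_grad():
            eval_logits = model.forward(graph.node_features, graph.edges, graph.weights)
            val_loss = cross_entropy(eval_logits, graph.labels, val_idx)
        val_pred = eval_logits.value[val_idx].argmax(axis=1)
        history.train_loss.append(train_loss_value)
        history.val_loss.append(float(val_loss.value))
        history.val_accuracy.append(float((val_pred == graph.labels[val_idx]).mean()))
        del eval_logits, val_loss
    history.peak_memory_mb = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss / 1024.0
    return model, history


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """Entry (i, j) counts true-class-i nodes predicted as class j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        return np.zeros((num_classes, num_classes), dtype=np.int64)
    if y_true.min() < 0 or y_true.max() >= num_classes or y_pred.min() < 0 or y_pred.max() >= num_classes:
        raise ValueError(f"labels out of range [0, {num_classes})")
    return _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))


def evaluate(model, graph: LearningGraph, mask: np.ndarray) -> Metrics:
    """Accuracy, per-class and macro/weighted precision/recall/F1, support,
    and confusion matrix on the masked nodes."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("evaluation mask is empty")
    y_true = graph.labels[idx]
    y_pred = predict(model, graph)[idx]
    num_classes = len(graph.label_names)
    labels = np.arange(num_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    macro_p, macro_r, macro_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    w_p, w_r, w_f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    return Metrics(
        accuracy=float((y_true == y_pred).mean()),
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        macro_precision=float(macro_p),
        macro_recall=float(macro_r),
        macro_f1=float(macro_f),
        weighted_precision=float(w_p),
        weighted_recall=float(w_r),
        weighted_f1=float(w_f),
        confusion=confusion_matrix(y_true, y_pred, num_classes),
        label_names=list(graph.label_names),
    )


def save_checkpoint(model, config: TrainConfig, path: str | Path) -> None:
    payload = {
        "arch": config.arch,
        "config": config.__dict__,
        "params": [p.value for p in model.params],
    }
    Path(path).write_bytes(pickle.dumps(payload))


def load_checkpoint(path: str | Path, in_dim: int, num_classes: int):
    payload = pickle.loads(Path(path).read_bytes())
    config = TrainConfig(**payload["config"])
    model = init_model(config.arch, in_dim, num_classes, config)
    if len(model.params) != len(payload["params"]):
        raise ValueError("checkpoint does not match architecture")
    for p, value in zip(model.params, payload["params"]):
        p.value = np.asarray(value)
    return model, config
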