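"""Joint training of the four class-capsule heads plus the reconstruction
regularizer.

Each head carries its own margin loss; because the heads' gradient paths are
disjoint above their shared primary capsules, summing the four losses
back-propagates each one independently into its own head.  The decoder adds
a small sum-squared reconstruction penalty.  Optimization is Adam at
learning rate 0.001; the best model by validation accuracy is checkpointed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .capsules import MarginLossParams, capsule_lengths, margin_loss, margin_loss_t
from .layers import Adam
from .model import ForwardOutput, TTDCapsNet
from .tensor import Tensor

__all__ = ["TrainConfig", "total_loss", "train_model", "evaluate_accuracy"]


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 64
    epochs: int = 20
    seed: int = 0
    recon_weight: float = 0.0005
    loss: MarginLossParams = field(default_factory=MarginLossParams)
    log_path: str = None  # optional JSON-lines per-epoch log

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be >= 0")


def _one_hot(labels, n_classes):
    labels = np.asarray(labels, dtype=int)
    return np.eye(n_classes, dtype=np.float32)[labels]


def total_loss(out: ForwardOutput, targets, batch, params: TrainConfig = None):
    """Summed four-head margin loss plus weighted reconstruction SSE.

    Returns (scalar, breakdown dict).  Works on the plain numpy fields of a
    forward output, so it can also score hand-set outputs.
    """
    params = params or TrainConfig()
    n_classes = out.head_lengths[0].shape[-1]
    targets = np.asarray(targets)
    # contract: 1-D arrays are integer class labels, 2-D arrays are one-hot rows
    if targets.ndim == 1:
        targets = _one_hot(targets, n_classes)
    breakdown = {}
    margin_sum = 0.0
    for i, lengths in enumerate(out.head_lengths):
        li = margin_loss(lengths, targets, params.loss)
        breakdown[f"margin_head_{i}"] = li
        margin_sum += li
    flat = np.asarray(batch, dtype=np.float64).reshape(len(out.reconstruction), -1)
    sse = float(((out.reconstruction - flat) ** 2).sum(axis=1).mean())
    breakdown["reconstruction_sse"] = sse
    total = margin_sum + params.recon_weight * sse
    breakdown["total"] = total
    return total, breakdown


def _total_loss_t(out: ForwardOutput, onehot, batch_flat, cfg: TrainConfig) -> Tensor:
    loss = None
    for lengths_t in out.head_length_tensors:
        li = margin_loss_t(lengths_t, onehot, cfg.loss)
        loss = li if loss is None else loss + li
    if cfg.recon_weight > 0:
        diff = out.reconstruction_tensor - Tensor(batch_flat)
        loss = loss + cfg.recon_weight * (diff ** 2).sum(axis=1).mean()
    return loss


def evaluate_accuracy(model: TTDCapsNet, images, labels, batch_size=100):
    """Fraction of correct argmax predictions, evaluated in eval mode."""
    was_training = model.training
    model.eval()
    correct = 0
    for start in range(0, len(images), batch_size):
        pred, _ = model.predict(images[start:start + batch_size])
        correct += int((pred == np.asarray(labels[start:start + batch_size])).sum())
    if was_training:
        model.train()
    return correct / len(images)


def train_model(model: TTDCapsNet, train_set, val_set, cfg: TrainConfig,
                checkpoint_dir="."):
    """Train with Adam; checkpoint whenever validation accuracy improves.

    train_set / val_set are (images, labels) with images (n, H, W, C) floats
    in [0, 1].  Returns (history, best_checkpoint_path); fully reproducible
    under cfg.seed (single-threaded).
    """
    train_x, train_y = train_set
    val_x, val_y = val_set
    train_x = np.asarray(train_x, dtype=np.float32)
    val_x = np.asarray(val_x, dtype=np.float32)
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    n_classes = model.cfg.n_classes
    os.makedirs(checkpoint_dir, exist_ok=True)
    best_path = os.path.join(checkpoint_dir, "best.npz")
    best_val = -1.0
    history = []
    log_f = open(cfg.log_path, "a") if cfg.log_path else None

    try:
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(len(train_x))
            epoch_loss, n_correct = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = train_x[idx], train_y[idx]
                onehot = _one_hot(yb, n_classes)
                out = model.forward(xb, mask_labels=onehot, need_tensors=True)
                loss = _total_loss_t(out, onehot, xb.reshape(len(xb), -1), cfg)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                scores = capsule_lengths(out.concat_caps)
                n_correct += int((scores.argmax(axis=1) == yb).sum())
            train_acc = n_correct / len(train_x)
            val_acc = evaluate_accuracy(model, val_x, val_y)
            record = {"epoch": epoch, "train_loss": epoch_loss / len(train_x),
                      "train_acc": train_acc, "val_acc": val_acc}
            history.append(record)
            if log_f:
                log_f.write(json.dumps(record) + "\n")
                log_f.flush()
            if val_acc > best_val:
                best_val = val_acc
                model.save(best_path)
    finally:
        if log_f:
            log_f.close()
    return history, best_path
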