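"""Mini-batch gradient-descent training of the foot-strike CNN.

The multi-class cross-entropy loss is minimized with plain (momentum-free)
mini-batch SGD under a stair-step learning-rate schedule: the rate is
constant within an epoch and multiplied by a decay factor at each epoch
end, lr(e) = lr0 * decay^e.  Published hyperparameters: lr0 = 1e-4,
decay = 0.95, batch size 36, 50 epochs for from-scratch training and 100
for transfer learning.

Transfer learning copies every layer of a pretrained model and continues
training on the new cohort; when the class count changes (8 classes for
aged mice -> 11 for young), the final layer cannot be copied verbatim and
is re-initialized at the new width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import model as M
from .data import DEFAULT_NOISE_SIGMA, augment_frames, make_batches
from .io import LabeledClip

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "DivergenceError",
    "cross_entropy_loss",
    "lr_at_epoch",
    "train",
    "transfer_train",
    "as_arrays",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; message names epoch and batch."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the published settings (lr0 1e-4, decay 0.95 per
    epoch, batch 36, 50 epochs; transfer runs use 100).  ``augment``
    expands the training set eight-fold (4 flips x {clean, noisy}) once,
    before the first epoch; the test side is never augmented.
    """

    lr0: float = 1e-4
    decay: float = 0.95
    batch_size: int = 36
    epochs: int = 50
    seed: int = 0
    augment: bool = False
    noise_sigma: float = DEFAULT_NOISE_SIGMA

    def __post_init__(self) -> None:
        if not 0 < self.decay <= 1:
            raise ValueError(f"decay must be in (0, 1], got {self.decay}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.lr0 <= 0:
            raise ValueError(f"lr0 must be positive, got {self.lr0}")


@dataclass
class TrainHistory:
    """Per-epoch training record plus the final held-out accuracy."""

    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: float | None = None
    test_within_1_accuracy: float | None = None

    def to_records(self) -> list[dict]:
        return [
            {"epoch": e, "lr": r, "loss": l, "train_accuracy": a}
            for e, r, l, a in zip(self.epoch, self.lr, self.loss, self.train_accuracy)
        ]


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stair-step schedule: lr0 * decay^epoch, constant within an epoch."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return config.lr0 * config.decay**epoch


def cross_entropy_loss(logits: np.ndarray, labels: Sequence[int]) -> float:
    """Mean negative log softmax-probability of the true class.

    Computed in log-space (shifted log-sum-exp), so extreme logits do not
    overflow.  Labels must lie in 0..n_classes-1.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.ndim != 2 or len(labels) != logits.shape[0]:
        raise ValueError("logits must be (n, n_classes) aligned with labels")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= logits.shape[1]:
        raise ValueError("label outside 0..n_classes-1")
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(len(labels)), labels].mean())


def _loss_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """(mean cross-entropy, d loss / d logits) for one mini-batch."""
    n = logits.shape[0]
    probs = M.softmax_probs(logits)
    loss = cross_entropy_loss(logits, labels)
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(logits.dtype)


def as_arrays(clips) -> tuple[np.ndarray, np.ndarray]:
    """Stack a sequence of LabeledClips (or an (X, y) pair) into arrays."""
    if isinstance(clips, tuple) and len(clips) == 2:
        X, y = clips
        return np.asarray(X), np.asarray(y)
    X = np.stack([c.stack.pixels for c in clips])
    y = np.array([c.label for c in clips], dtype=np.int64)
    return X, y


def _sgd_step(params: M.ModelParams, grads: M.ModelParams, lr: float) -> None:
    for p, g in zip(params.tensors(), grads.tensors()):
        p -= lr * g


def _augment_training_set(
    X: np.ndarray, y: np.ndarray, noise_sigma: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Static eight-fold expansion applied once before the first epoch."""
    children = np.random.SeedSequence(seed).spawn(len(X))
    out_X, out_y = [], []
    for pixels, label, child in zip(X, y, children):
        clip_seed = int(child.generate_state(1)[0] % (2**31))
        out_X.extend(augment_frames(pixels, noise_sigma, clip_seed))
        out_y.extend([label] * 8)
    return np.stack(out_X), np.asarray(out_y)


def _run_training(
    params: M.ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray | None,
    y_test: np.ndarray | None,
    config: TrainConfig,
) -> TrainHistory:
    history = TrainHistory()
    dtype = np.dtype(params.config.dtype)
    X = np.ascontiguousarray(X, dtype=dtype)
    epoch_seeds = np.random.SeedSequence(config.seed).generate_state(max(config.epochs, 1))
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        batches = make_batches(
            np.arange(len(X)), config.batch_size, int(epoch_seeds[epoch] % (2**31))
        )
        losses = []
        correct = 0
        for b, batch_idx in enumerate(batches):
            logits, cache = M.forward_with_cache(params, X[batch_idx])
            loss, dlogits = _loss_grad(logits, y[batch_idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, batch {b} (lr={lr:g})"
                )
            grads = M.backward(params, cache, dlogits)
            _sgd_step(params, grads, lr)
            losses.append(loss * len(batch_idx))
            correct += int((logits.argmax(axis=1) == y[batch_idx]).sum())
        mean_loss = float(np.sum(losses) / len(X))
        train_acc = correct / len(X)
        history.epoch.append(epoch)
        history.lr.append(lr)
        history.loss.append(mean_loss)
        history.train_accuracy.append(train_acc)
        logger.info(
            "epoch %d: lr=%.3g loss=%.4f train_acc=%.3f", epoch, lr, mean_loss, train_acc
        )
    if X_test is not None and len(X_test):
        preds = predict_in_batches(params, X_test, config.batch_size)
        history.test_accuracy = float((preds == y_test).mean())
        history.test_within_1_accuracy = float((np.abs(preds - y_test) <= 1).mean())
        logger.info(
            "test: exact=%.3f within-1Hz=%.3f",
            history.test_accuracy,
            history.test_within_1_accuracy,
        )
    return history


def predict_in_batches(
    params: M.ModelParams, X: np.ndarray, batch_size: int = 36
) -> np.ndarray:
    """Memory-bounded batched prediction."""
    preds = [
        M.predict_batch(params, X[i : i + batch_size])
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


def train(
    clips,
    test_clips,
    model_config: M.ModelConfig,
    train_config: TrainConfig,
) -> tuple[M.ModelParams, TrainHistory]:
    """Train the CNN from random initialization.

    ``clips``/``test_clips`` may be sequences of :class:`LabeledClip` or
    ``(X, y)`` array pairs.  Fully reproducible given the seeds embedded
    in the configs: parameter initialization, the optional augmentation
    noise, and each epoch's shuffle all derive from ``train_config.seed``.
    """
    X, y = as_arrays(clips)
    if len(X) == 0:
        raise ValueError("empty training set")
    if y.max() >= model_config.n_classes:
        raise ValueError(
            f"label {y.max()} out of range for n_classes={model_config.n_classes}"
        )
    X_test, y_test = (None, None) if test_clips is None else as_arrays(test_clips)
    if train_config.augment:
        X, y = _augment_training_set(X, y, train_config.noise_sigma, train_config.seed)
    params = M.init_params(model_config, train_config.seed)
    history = _run_training(params, X, y, X_test, y_test, train_config)
    return params, history


def transfer_train(
    pretrained: M.ModelParams,
    clips,
    test_clips,
    new_n_classes: int,
    train_config: TrainConfig,
) -> tuple[M.ModelParams, TrainHistory]:
    """Fine-tune a pretrained model on a new cohort.

    All layers are copied from ``pretrained``.  If ``new_n_classes``
    differs from the pretrained output width, the final fully connected
    layer is re-initialized at the new width (a verbatim copy is
    shape-impossible); every other layer starts from the pretrained
    weights and all layers remain trainable.
    """
    old_cfg = pretrained.config
    cfg_kwargs = dict(
        n_classes=new_n_classes,
        input_shape=old_cfg.input_shape,
        conv_channels=old_cfg.conv_channels,
        kernel_size=old_cfg.kernel_size,
        pool_window=old_cfg.pool_window,
        pool_stride=old_cfg.pool_stride,
        leaky_slope=old_cfg.leaky_slope,
        fc_hidden=old_cfg.fc_hidden,
        dtype=old_cfg.dtype,
    )
    new_cfg = M.ModelConfig(**cfg_kwargs)
    params = pretrained.copy()
    params.config = new_cfg
    if new_n_classes != old_cfg.n_classes:
        fresh = M.init_params(new_cfg, train_config.seed)
        params.fc_w[2] = fresh.fc_w[2]
        params.fc_b[2] = fresh.fc_b[2]
        logger.info(
            "transfer: final layer re-initialized for %d -> %d classes",
            old_cfg.n_classes,
            new_n_classes,
        )
    params.validate()
    X, y = as_arrays(clips)
    if len(X) == 0:
        raise ValueError("empty training set")
    if train_config.augment:
        X, y = _augment_training_set(X, y, train_config.noise_sigma, train_config.seed)
    X_test, y_test = (None, None) if test_clips is None else as_arrays(test_clips)
    history = _run_training(params, X, y, X_test, y_test, train_config)
    return params, history
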