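"""SGD training loop with early stopping, plus deep-feature extraction.

Training minimizes the softmax cross-entropy with stochastic gradient
descent (classical momentum).  Per-epoch train/validation loss and accuracy
are recorded; the weights with the best validation accuracy are kept.  All
randomness (batch shuffling) comes from the config seed, so a run is fully
reproducible on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import TrainingError
from . import layers as L
from .networks import SpectralNetwork


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 300
    patience: int = 30          # early stop on validation accuracy
    rng_seed: int = 0
    standardize: bool = True    # per-band z-scoring fit on the training set

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class DeepFeatures:
    """Row-aligned deep features with their class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    source: str                 # "cnn-dense2" or "resnet-gap"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("deep features must be finite")


def _evaluate(model: SpectralNetwork, X: np.ndarray, y: np.ndarray,
              loss_fn: L.SoftmaxCrossEntropy, batch_size: int = 512
              ) -> tuple[float, float]:
    losses, hits, n = [], 0, X.shape[0]
    for i in range(0, n, batch_size):
        logits = model.forward(model._prepare(X[i:i + batch_size]))
        yb = y[i:i + batch_size]
        losses.append(loss_fn.forward(logits, yb) * yb.size)
        hits += int((logits.argmax(axis=1) == yb).sum())
    return sum(losses) / n, 100.0 * hits / n


def train(model: SpectralNetwork, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          config: TrainingConfig = TrainingConfig()) -> TrainingHistory:
    """Train in place; returns the per-epoch history.  The parameters giving
    the best validation accuracy are restored before returning."""
    X_train = np.asarray(X_train, dtype=L.DTYPE)
    X_val = np.asarray(X_val, dtype=L.DTYPE)
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if X_train.shape[1] != X_val.shape[1]:
        raise ValueError("train and validation feature dimensionality differ")
    if config.standardize:
        mean = X_train.mean(axis=0)
        scale = X_train.std(axis=0)
        scale[scale == 0] = 1.0
        model.band_mean = mean.astype(L.DTYPE)
        model.band_scale = scale.astype(L.DTYPE)

    rng = np.random.default_rng(config.rng_seed)
    loss_fn = L.SoftmaxCrossEntropy()
    optimizer = L.SGD(model.params(), lr=config.learning_rate,
                      momentum=config.momentum)
    history = TrainingHistory()
    best_val, best_snap, since_best = -np.inf, model.snapshot(), 0
    n = X_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_hits = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = model._prepare(X_train[idx])
            yb = y_train[idx]
            logits = model.forward(xb, train=True)
            loss = loss_fn.forward(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(loss_fn.backward())
            optimizer.step()
            epoch_loss += loss * yb.size
            epoch_hits += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(100.0 * epoch_hits / n)
        val_loss, val_acc = _evaluate(model, X_val, y_val, loss_fn)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if val_acc > best_val:
            best_val, best_snap, since_best = val_acc, model.snapshot(), 0
            history.best_epoch = epoch + 1
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.restore(best_snap)
    model.trained = True
    return history


def extract_features(model: SpectralNetwork, X: np.ndarray,
                     labels: np.ndarray) -> DeepFeatures:
    """Deep features from the designated layer: the activated second dense
    layer for the self-design CNN (128-d, nonnegative) or the global average
    pooling output for ResNet-1D (512-d)."""
    source = ("cnn-dense2" if model.spec.architecture == "self-design-cnn"
              else "resnet-gap")
    return DeepFeatures(matrix=model.features(np.asarray(X)),
                        labels=np.asarray(labels, dtype=int), source=source)
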