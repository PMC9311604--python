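"""Within-subject training loop.

Fixed global hyperparameters across subjects: Adam (lr 0.0009, beta1 0.9,
beta2 0.999, eps 1e-7), batch size 64, categorical cross-entropy, 1000
epochs by default.  No early stopping, learning-rate schedule or validation
split.  Shuffling and dropout are reseeded per epoch from the spec seed, so
a run is fully reproducible on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TrialSet
from .model import Model
from .nn import softmax

__all__ = ["TrainSpec", "TrainingHistory", "cross_entropy", "train"]

_PROB_FLOOR = 1e-12


@dataclass
class TrainSpec:
    """Global training hyperparameters (identical for every subject)."""

    learning_rate: float = 0.0009
    batch_size: int = 64
    epochs: int = 1000
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate, batch_size must be positive; epochs >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss and accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.loss)


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, -log p(true class), floored at 1e-12."""
    probabilities = np.asarray(probabilities)
    labels = np.asarray(labels)
    n, k = probabilities.shape
    if labels.shape != (n,):
        raise ValueError("one label per probability row required")
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in [0, {k})")
    p_true = probabilities[np.arange(n), labels]
    return float(-np.log(np.clip(p_true, _PROB_FLOOR, None)).mean())


def train(model: Model, trainset: TrialSet, spec: TrainSpec | None = None,
          log_fn=None) -> TrainingHistory:
    """Train in place with Adam; returns the per-epoch history.

    Batches are drawn from a fresh per-epoch shuffle seeded from
    ``(spec.seed, epoch)``; the last partial batch is kept.  ``epochs = 0``
    leaves the parameters untouched.
    """
    spec = spec or TrainSpec()
    if trainset.n_trials == 0:
        raise ValueError("cannot train on an empty trial set")
    if trainset.labels.max() >= model.n_classes:
        raise ValueError(
            f"label {trainset.labels.max()} outside [0, {model.n_classes})")
    x = trainset.trials.astype(model.dtype, copy=False)
    y = trainset.labels
    n = x.shape[0]
    params = model.trainable_params()
    m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
    v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
    step = 0
    history = TrainingHistory()
    for epoch in range(spec.epochs):
        rng = np.random.default_rng([spec.seed % (2 ** 31), epoch])
        order = rng.permutation(n)
        losses, n_correct = [], 0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, training=True, rng=rng)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, yb) * len(idx))
            n_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(idx)), yb] -= 1.0
            dlogits /= len(idx)
            model.zero_grad()
            model.backward(dlogits.astype(model.dtype))
            step += 1
            lr_t = spec.learning_rate * np.sqrt(1 - spec.beta2 ** step) / (1 - spec.beta1 ** step)
            for p, mi, vi in zip(params, m, v):
                g = p.grad.astype(np.float64)
                mi += (1 - spec.beta1) * (g - mi)
                vi += (1 - spec.beta2) * (g * g - vi)
                p.value -= (lr_t * mi / (np.sqrt(vi) + spec.epsilon)).astype(p.value.dtype)
        history.loss.append(sum(losses) / n)
        history.accuracy.append(n_correct / n)
        if log_fn is not None:
            log_fn(epoch, history.loss[-1], history.accuracy[-1])
    return history
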