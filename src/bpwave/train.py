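"""Training engine: splits, schedules, optimization, history logging.

The optimizer is the adaptive-moment scheme identified by its printed
constants (decay 0.9 / 0.999, epsilon 1e-8) with classical coupled L2
regularization and global L2-norm gradient clipping; the learning rate
follows a piecewise step-decay schedule.  Per-epoch RMSE is reported
in mmHg by inverting the z-scored labels with the global pressure
statistics.  Two named profiles bundle the hyperparameters: ``paper``
carries the full published settings (7000 epochs, mini-batch 1 for the
convolutional model), ``desk`` a small-scale configuration that trains
in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import Adam, piecewise_lr
from .models import half_mse_loss
from .preprocess import invert_labels

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PROFILES",
    "split_frames",
    "train_model",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults: convolutional model)."""

    learn_rate: float = 1e-4
    gradient_decay: float = 0.9
    squared_gradient_decay: float = 0.999
    epsilon: float = 1e-8
    drop_factor: float = 0.01
    drop_period: int = 125_000
    l2_regularization: float = 1e-4
    gradient_clip: float = 1.0
    max_epochs: int = 7000
    mini_batch: int = 1
    shuffle: str = "every-epoch"
    seed: int = 0
    validation_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("epsilon", "drop_period", "max_epochs", "mini_batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learn_rate < 0:
            raise ValueError("learn_rate must be non-negative")
        if not 0 < self.drop_factor <= 1:
            raise ValueError(f"drop_factor must be in (0, 1], got {self.drop_factor}")
        if not 0 < self.validation_fraction < 0.5:
            raise ValueError(
                f"validation_fraction must be in (0, 0.5), got {self.validation_fraction}"
            )
        if self.shuffle not in ("every-epoch", "once"):
            raise ValueError(f"shuffle must be 'every-epoch' or 'once', got {self.shuffle!r}")


#: named hyperparameter bundles; "paper" is the published full-scale
#: setting, "desk" a CPU-minutes configuration for the same pipeline
PROFILES: dict[str, dict] = {
    "paper": {
        "can": TrainConfig(),
        "lstm": TrainConfig(learn_rate=5e-3, mini_batch=2, shuffle="once"),
        "can_channels": 32,
        "lstm_hidden": 400,
    },
    "desk": {
        "can": TrainConfig(learn_rate=3e-3, max_epochs=40, mini_batch=8),
        "lstm": TrainConfig(learn_rate=5e-3, max_epochs=40, mini_batch=8,
                            shuffle="once"),
        "can_channels": 8,
        "lstm_hidden": 32,
    },
}


@dataclass
class TrainHistory:
    """Per-epoch training trace."""

    loss: list[float] = field(default_factory=list)
    train_rmse_mmhg: list[float] = field(default_factory=list)
    val_rmse_mmhg: list[float] = field(default_factory=list)
    learn_rate: list[float] = field(default_factory=list)
    iterations: int = 0

    def __len__(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "loss": self.loss,
                "train_rmse_mmhg": self.train_rmse_mmhg,
                "val_rmse_mmhg": self.val_rmse_mmhg,
                "learn_rate": self.learn_rate,
            }
        )


def split_frames(
    n_frames: int,
    mode: str = "random",
    counts: tuple[int, ...] | None = None,
    fractions: tuple[float, ...] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition frame indices into (train, validation, test) sets.

    ``counts`` gives explicit sizes (must sum to ``n_frames``);
    ``fractions`` gives proportions (2 entries -> train/validation with
    an empty test set; remainders after flooring go to the training
    set).  ``mode='random'`` permutes indices reproducibly from
    ``seed``; ``mode='sequential'`` keeps source order, first block
    train, last block test.
    """
    if mode not in ("random", "sequential"):
        raise ValueError(f"mode must be 'random' or 'sequential', got {mode!r}")
    if (counts is None) == (fractions is None):
        raise ValueError("provide exactly one of counts= or fractions=")
    if counts is None:
        fracs = tuple(fractions)
        if len(fracs) == 2:
            fracs = (*fracs, 0.0)
        if len(fracs) != 3 or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must have 2 or 3 entries summing to 1, got {fractions}")
        n_val = int(n_frames * fracs[1])
        n_test = int(n_frames * fracs[2])
        counts = (n_frames - n_val - n_test, n_val, n_test)
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts) or sum(counts) != n_frames:
        raise ValueError(
            f"counts {counts} must be 3 non-negative integers summing to {n_frames}"
        )
    if mode == "random":
        order = np.random.default_rng(seed).permutation(n_frames)
    else:
        order = np.arange(n_frames)
    n_train, n_val, _ = counts
    return (
        order[:n_train],
        order[n_train:n_train + n_val],
        order[n_train + n_val:],
    )


def _rmse_mmhg(model, X, y, stats) -> float:  # noqa: N803
    pred = model.predict(X)
    pred_mmhg = invert_labels(pred, stats)
    y_mmhg = invert_labels(y, stats)
    return float(np.sqrt(np.mean((pred_mmhg - y_mmhg) ** 2)))


def train_model(
    model,
    inputs: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    abp_stats: tuple[float, float] = (0.0, 1.0),
    val_inputs: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    augment=None,
    callback=None,
) -> TrainHistory:
    """Optimize ``model`` in place and return its per-epoch history.

    ``model`` is any network exposing forward/backward/parameters
    (:class:`~bpwave.models.CANNetwork` or
    :class:`~bpwave.models.LSTMNetwork`).  ``abp_stats`` are the global
    (mean, std) used to report RMSE in mmHg; with the default identity
    stats the RMSE is in label units.  ``augment``, if given, is
    called as ``augment(epoch, rng) -> inputs`` before each epoch to
    re-draw the amplitude randomization on fresh gains.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(inputs) != len(labels):
        raise ValueError(f"{len(inputs)} inputs vs {len(labels)} labels")
    if len(inputs) == 0:
        raise ValueError("empty training set")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(
        beta1=cfg.gradient_decay,
        beta2=cfg.squared_gradient_decay,
        eps=cfg.epsilon,
        l2=cfg.l2_regularization,
        grad_clip=cfg.gradient_clip,
    )
    named_params = model.parameters()
    history = TrainHistory()
    n = len(inputs)
    order = rng.permutation(n) if cfg.shuffle == "once" else np.arange(n)

    for epoch in range(cfg.max_epochs):
        if augment is not None:
            inputs = np.asarray(augment(epoch, rng), dtype=np.float64)
        if cfg.shuffle == "every-epoch":
            order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.mini_batch):
            batch = order[start:start + cfg.mini_batch]
            xb, yb = inputs[batch], labels[batch]
            pred = model.forward(xb, training=True)
            loss = half_mse_loss(yb, pred)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch + 1}"
                )
            model.zero_grad()
            model.backward((pred - yb) / len(batch))
            lr = piecewise_lr(cfg.learn_rate, cfg.drop_factor, cfg.drop_period,
                              history.iterations)
            optimizer.step(named_params, lr)
            history.iterations += 1
            epoch_losses.append(loss)
        history.loss.append(float(np.mean(epoch_losses)))
        history.train_rmse_mmhg.append(_rmse_mmhg(model, inputs, labels, abp_stats))
        if val_inputs is not None and len(val_inputs):
            history.val_rmse_mmhg.append(
                _rmse_mmhg(model, val_inputs, val_labels, abp_stats))
        else:
            history.val_rmse_mmhg.append(float("nan"))
        history.learn_rate.append(
            piecewise_lr(cfg.learn_rate, cfg.drop_factor, cfg.drop_period,
                         max(history.iterations - 1, 0)))
        if callback is not None:
            callback(epoch, history)
    return history
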