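"""Training protocols: losses, optimizers, schedules and the trainer.

The reference protocols are: plain stacked-conv baseline trained with Adam
(lr 1e-3) and MSE for 400 fixed epochs; every other family with AdamW
(lr 8e-4, weight decay 1e-4), Huber loss (delta = 1.0), early stopping with
best-weight restoration (patience 30) and reduce-on-plateau (factor 0.5,
patience 10, min lr 1e-6); batch size 128, seed 42. A documented "fast"
profile with reduced epoch/patience budgets is provided for desk-scale
experiments; it changes no optimizer hyperparameter.

Gradients come from the package's own numpy backward pass (edgebp.nn); the
scheduler and early stopper are pure functions of the validation-loss
sequence and are unit-testable without any training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from edgebp.graph import WEIGHTED, ArchitectureSpec
from edgebp.nn import FloatModel, backward_batch, cast_model, forward_batch, init_weights
from edgebp.preprocess import SplitDataset

log = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def huber_loss(errors: np.ndarray, delta: float = 1.0) -> float:
    """Mean Huber loss over all error elements.

    Per element: e^2/2 for |e| <= delta, else delta*|e| - delta^2/2; the
    two branches agree at the knee. Reduction is the unweighted mean over
    both outputs and all samples.
    """
    if delta <= 0:
        raise TrainingError("delta must be > 0")
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0 or not np.isfinite(e).all():
        raise TrainingError("errors must be non-empty and finite")
    a = np.abs(e)
    per = np.where(a <= delta, 0.5 * e**2, delta * a - 0.5 * delta**2)
    return float(per.mean())


def mse_loss(errors: np.ndarray) -> float:
    e = np.asarray(errors, dtype=np.float64)
    if e.size == 0:
        raise TrainingError("empty error array")
    return float((e**2).mean())


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, loss: str, delta: float):
    """Loss value and d(loss)/d(pred) with e = target - pred."""
    e = target - pred
    n = e.size
    if loss == "huber":
        a = np.abs(e)
        val = float(np.where(a <= delta, 0.5 * e**2, delta * a - 0.5 * delta**2).mean())
        psi = np.where(a <= delta, e, delta * np.sign(e))
        return val, (-psi / n).astype(pred.dtype)
    val = float((e**2).mean())
    return val, (-2.0 * e / n).astype(pred.dtype)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    optimizer: str = "adamw"  # {adam, adamw}
    learning_rate: float = 8e-4
    weight_decay: float = 1e-4
    loss: str = "huber"  # {mse, huber}
    huber_delta: float = 1.0
    batch_size: int = 128
    max_epochs: int = 400
    early_stop_patience: Optional[int] = 30
    restore_best: bool = True
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-6
    seed: int = 42

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.huber_delta <= 0 or self.batch_size < 1:
            raise TrainingError("invalid training configuration")
        if self.optimizer not in ("adam", "adamw") or self.loss not in ("mse", "huber"):
            raise TrainingError("unknown optimizer or loss")


def default_config(name: str) -> TrainConfig:
    """Reference protocol per architecture family."""
    if name == "baseline_cnn":
        return TrainConfig(
            optimizer="adam",
            learning_rate=1e-3,
            weight_decay=0.0,
            loss="mse",
            max_epochs=400,
            early_stop_patience=None,
            restore_best=False,
        )
    from edgebp.zoo import ARCHITECTURE_NAMES

    if name not in ARCHITECTURE_NAMES:
        raise KeyError(f"unknown architecture {name!r}")
    return TrainConfig()


def fast_profile(name: str) -> TrainConfig:
    """Desk-scale profile: reduced epoch/patience caps, same optimizer.

    Only the early-stopping architectures are capped: their epoch budget is
    a ceiling, not a regime. The baseline's fixed-epoch MSE schedule is the
    regime itself (training well past convergence is what shapes its weight
    and activation ranges), so it keeps its full 400 epochs.
    """
    cfg = default_config(name)
    if name == "baseline_cnn":
        return cfg
    return replace(cfg, max_epochs=60, early_stop_patience=12, plateau_patience=5)


# ---------------------------------------------------------------------------
# Scheduler / stopper (pure functions of the val-loss sequence)
# ---------------------------------------------------------------------------


class PlateauScheduler:
    """Halve the learning rate after ``patience`` epochs without improvement,
    floored at ``min_lr``."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 10, min_lr: float = 1e-6):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait > self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


class EarlyStopper:
    """Stop after ``patience`` epochs without validation improvement."""

    def __init__(self, patience: Optional[int]):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.patience is not None and self.wait > self.patience


def schedule_trajectory(
    val_losses: Sequence[float], lr0: float, factor: float, patience: int, min_lr: float
) -> list[float]:
    """Learning-rate trajectory for a scripted val-loss sequence."""
    sched = PlateauScheduler(lr0, factor, patience, min_lr)
    return [sched.update(v) for v in val_losses]


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class _AdamState:
    def __init__(self, weights: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: {p: np.zeros_like(v) for p, v in wb.items()} for k, wb in weights.items()}
        self.v = {k: {p: np.zeros_like(v) for p, v in wb.items()} for k, wb in weights.items()}

    def step(self, weights: dict, grads: dict, lr: float, weight_decay: float, decoupled: bool):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            for p in ("w", "b"):
                gv = g[p]
                m = self.m[k][p]
                v = self.v[k][p]
                m += (1 - self.beta1) * (gv - m)
                v += (1 - self.beta2) * (gv * gv - v)
                update = lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
                if decoupled and weight_decay > 0 and p == "w":
                    update = update + lr * weight_decay * weights[k][p]
                weights[k][p] -= update


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: FloatModel  # best-validation weights (float64)
    history: dict  # per-epoch train/val loss and learning rate
    stopped_epoch: int


def train_model(spec: ArchitectureSpec, data: SplitDataset, config: TrainConfig) -> TrainResult:
    """Mini-batch gradient training of one architecture on a split dataset.

    Runs in float32 for speed; the returned model is cast to float64 and is
    executable by the neutral reference executor. Divergence (non-finite
    loss) aborts with a diagnostic.
    """
    config.validate()
    if len(data.train) == 0 or len(data.val) == 0:
        raise TrainingError("train and val splits must be non-empty")

    rng = np.random.default_rng(config.seed)
    model = init_weights(spec, seed=config.seed, dtype=np.float32)
    Xtr = np.ascontiguousarray(data.train.values[:, :, None], dtype=np.float32)
    ytr = np.column_stack([data.train.sbp, data.train.dbp]).astype(np.float32)
    Xva = np.ascontiguousarray(data.val.values[:, :, None], dtype=np.float32)
    yva = np.column_stack([data.val.sbp, data.val.dbp]).astype(np.float32)

    opt = _AdamState(model.weights)
    sched = PlateauScheduler(config.learning_rate, config.plateau_factor, config.plateau_patience, config.min_lr)
    stopper = EarlyStopper(config.early_stop_patience)
    decoupled = config.optimizer == "adamw"
    best_weights = None
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    lr = config.learning_rate
    stopped = config.max_epochs - 1

    n = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            out, acts = forward_batch(model, Xtr[idx], want_cache=True)
            loss, gout = _loss_and_grad(out, ytr[idx], config.loss, config.huber_delta)
            if not np.isfinite(loss):
                raise TrainingError(f"divergence at epoch {epoch}: non-finite loss")
            grads = backward_batch(model, acts, gout)
            opt.step(model.weights, grads, lr, config.weight_decay, decoupled)
            epoch_loss += loss * idx.size
        epoch_loss /= n

        val_out, _ = forward_batch(model, Xva)
        val_loss, _ = _loss_and_grad(val_out, yva, config.loss, config.huber_delta)
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(float(val_loss))
        history["lr"].append(lr)
        log.debug("epoch %d train %.4f val %.4f lr %.2e", epoch, epoch_loss, val_loss, lr)

        improved = val_loss < stopper.best - 1e-12
        stop = stopper.update(val_loss, epoch)
        if improved and config.restore_best:
            best_weights = {k: {p: v.copy() for p, v in wb.items()} for k, wb in model.weights.items()}
        lr = sched.update(val_loss)
        if stop:
            stopped = epoch
            break
    else:
        stopped = config.max_epochs - 1

    if config.restore_best and best_weights is not None:
        model = FloatModel(spec=spec, weights=best_weights)
    return TrainResult(model=cast_model(model, np.float64), history=history, stopped_epoch=stopped)
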