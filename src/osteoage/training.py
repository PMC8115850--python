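"""Training loop: MSE objective, Adam, plateau LR schedule, crop augmentation.

Optimization follows the regression recipe the architecture is built for:
mean-squared error on chronological age, Adam with first-moment coefficient
0.9 and L2 weight decay 1e-4, minibatches of 16, learning rate starting at
3e-4 and reduced by a factor 0.8 whenever the validation loss has plateaued
for 10 consecutive epochs, floored at 3e-5, for up to 50 epochs. Data
augmentation is random cropping of the bone voxels (defaults: mandible
20x224x224, femur 112x112x112); evaluation uses deterministic center crops.
The checkpointed model is the epoch with the best validation MAE.

Progressive input-size pretraining trains the same architecture on a ladder
of growing input shapes, carrying every shape-compatible parameter from one
rung to the next.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .networks import LateFusionEnsemble, NetworkConfig, build_model

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Sample",
    "TrainingDivergedError",
    "mse_loss",
    "random_crop",
    "center_crop",
    "PlateauScheduler",
    "lr_schedule_step",
    "evaluate",
    "train",
    "train_late_ensemble",
    "progressive_pretrain",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class Sample:
    """One subject's training record: id, age (years), sex code, voxels."""

    sid: str
    age: float
    sex: int
    voxels: dict[str, np.ndarray]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    lr: float = 3e-4
    min_lr: float = 3e-5
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    plateau_factor: float = 0.8
    plateau_patience: int = 10
    plateau_rel_threshold: float = 1e-3
    crop_shapes: dict = field(
        default_factory=lambda: {
            "mandible": (20, 224, 224),
            "femur": (112, 112, 112),
            "early": (64, 112, 112),
        }
    )
    init_head_bias_to_mean: bool = True
    shuffle: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.min_lr > self.lr:
            raise ValueError("min LR must not exceed the initial LR")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau factor must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def mse_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error ``(1/n) * sum((y_i - yhat_i)^2)``."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between true and predicted ages")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - yhat) ** 2))


def _spatial_slices(src: tuple[int, ...], target: tuple[int, ...], offsets) -> tuple[slice, ...]:
    return tuple(slice(o, o + t) for o, t in zip(offsets, target))


def random_crop(voxel: np.ndarray, target: tuple[int, int, int], rng: np.random.Generator):
    """Uniformly positioned contiguous crop of the trailing three axes."""
    spatial = voxel.shape[-3:]
    if any(t > s for t, s in zip(target, spatial)):
        raise ValueError(f"crop too large: target {target} exceeds source {spatial}")
    offsets = [int(rng.integers(0, s - t + 1)) for s, t in zip(spatial, target)]
    lead = (slice(None),) * (voxel.ndim - 3)
    return voxel[lead + _spatial_slices(spatial, target, offsets)]


def center_crop(voxel: np.ndarray, target: tuple[int, int, int]):
    """Deterministic central crop used at evaluation time."""
    spatial = voxel.shape[-3:]
    if any(t > s for t, s in zip(target, spatial)):
        raise ValueError(f"crop too large: target {target} exceeds source {spatial}")
    offsets = [(s - t) // 2 for s, t in zip(spatial, target)]
    lead = (slice(None),) * (voxel.ndim - 3)
    return voxel[lead + _spatial_slices(spatial, target, offsets)]


class PlateauScheduler:
    """Reduce-on-plateau: LR * factor after ``patience`` stalled epochs.

    An epoch counts as stalled when the validation loss fails to improve on
    the running best by more than a relative threshold. The first epoch of a
    flat run counts toward the plateau, so ten identical losses trigger one
    reduction. The LR never drops below ``min_lr``.
    """

    def __init__(self, lr, factor=0.8, patience=10, min_lr=3e-5, rel_threshold=1e-3):
        self.lr = lr
        self.factor, self.patience = factor, patience
        self.min_lr, self.rel_threshold = min_lr, rel_threshold
        self.best: float | None = None
        self.num_bad = 0

    def step(self, val_loss: float) -> float:
        if self.best is None:
            self.best = val_loss
            self.num_bad = 1
        elif val_loss < self.best * (1 - self.rel_threshold):
            self.best = val_loss
            self.num_bad = 0
        else:
            self.best = min(self.best, val_loss)
            self.num_bad += 1
        if self.num_bad >= self.patience:
            self.lr = max(self.lr * self.factor, self.min_lr)
            self.num_bad = 0
        return self.lr


def lr_schedule_step(val_losses, current_lr: float, config: TrainConfig) -> float:
    """Next LR given the validation-loss history (see :class:`PlateauScheduler`)."""
    if len(val_losses) == 0:
        raise ValueError("need at least one validation loss")
    best: float | None = None
    num_bad = 0
    for loss in val_losses:
        if best is None:
            best, num_bad = loss, 1
        elif loss < best * (1 - config.plateau_rel_threshold):
            best, num_bad = loss, 0
        else:
            best = min(best, loss)
            num_bad += 1
    if num_bad >= config.plateau_patience:
        return max(current_lr * config.plateau_factor, config.min_lr)
    return current_lr


def _make_batch(samples, indices, modalities, crop, cropper) -> dict:
    batch: dict = {
        "sex": np.array([samples[i].sex for i in indices]),
    }
    for m in modalities:
        arrays = []
        for i in indices:
            v = samples[i].voxels[m]
            if v.ndim == 3:
                v = v[None]  # add channel axis
            arrays.append(cropper(v, crop[m]))
        batch[m] = np.stack(arrays).astype(np.float32)
    return batch


def evaluate(model, samples, config: TrainConfig) -> np.ndarray:
    """Center-cropped, eval-mode predictions for ``samples`` (in order)."""
    modalities = model.modalities
    preds = []
    for start in range(0, len(samples), config.batch_size):
        idx = range(start, min(start + config.batch_size, len(samples)))
        batch = _make_batch(samples, idx, modalities, config.crop_shapes, center_crop)
        preds.append(model.predict(batch))
    return np.concatenate(preds)


def train(model, train_samples, val_samples, config: TrainConfig):
    """Fit ``model`` by minibatch Adam on MSE; return (model, history).

    The model is restored to the epoch with the lowest validation MAE
    (earlier epoch on ties). Fully seeded: data order, crop offsets and
    parameter initialization are all reproducible.
    """
    config.validate()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(config.seed)
    modalities = model.modalities
    ages = np.array([s.age for s in train_samples], dtype=np.float64)
    val_ages = np.array([s.age for s in val_samples], dtype=np.float64)
    if config.init_head_bias_to_mean:
        model.set_head_bias(float(ages.mean()))

    opt = nn.Adam(
        model.parameters(),
        lr=config.lr,
        beta1=config.beta1,
        beta2=config.beta2,
        weight_decay=config.weight_decay,
    )
    sched = PlateauScheduler(
        config.lr,
        config.plateau_factor,
        config.plateau_patience,
        config.min_lr,
        config.plateau_rel_threshold,
    )
    history = TrainHistory()
    best_mae = np.inf
    best_state = nn.state_dict(model)

    n = len(train_samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _make_batch(train_samples, idx, modalities, config.crop_shapes,
                                lambda v, t: random_crop(v, t, rng))
            y = ages[idx]
            yhat = model.forward_batch(batch, train=True)
            loss = mse_loss(y, yhat)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(((yhat - y) * (2.0 / len(y))).astype(np.float32))
            opt.step()
            epoch_loss += loss * len(y)
        epoch_loss /= n

        val_pred = evaluate(model, val_samples, config)
        val_loss = mse_loss(val_ages, val_pred)
        val_mae = float(np.mean(np.abs(val_ages - val_pred)))
        opt.lr = sched.step(val_loss)

        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        history.val_mae.append(val_mae)
        history.lr.append(opt.lr)
        if val_mae < best_mae:
            best_mae = val_mae
            best_state = nn.state_dict(model)
            history.best_epoch = epoch

    nn.load_state_dict(model, best_state)
    return model, history


def train_late_ensemble(ensemble: LateFusionEnsemble, train_samples, val_samples, config):
    """Train the two submodels of a late-fusion ensemble independently."""
    histories = {}
    for i, (tag, sub) in enumerate(ensemble.submodels.items()):
        _, histories[tag] = train(sub, train_samples, val_samples, replace(config, seed=config.seed + i))
    return ensemble, histories


def progressive_pretrain(rungs, datasets):
    """Train through a ladder of input sizes, transferring weights upward.

    ``rungs`` is a list of ``(NetworkConfig, TrainConfig)`` pairs ordered
    small to large; ``datasets`` supplies ``(train_samples, val_samples)``
    per rung (the voxels must match each rung's input scale). All parameters
    whose name and shape match are carried to the next rung; anything
    shape-incompatible (e.g. a head over a different feature width) keeps
    its fresh seeded initialization.

    Returns ``(model, histories, transfer_logs)``.
    """
    if len(rungs) != len(datasets) or len(rungs) == 0:
        raise ValueError("transfer mismatch: need one dataset per ladder rung")
    model = None
    histories, transfer_logs = [], []
    prev_state: dict | None = None
    for (net_cfg, train_cfg), (tr, va) in zip(rungs, datasets):
        model = build_model(net_cfg)
        if isinstance(model, LateFusionEnsemble):
            raise ValueError("transfer mismatch: progressive ladder expects a joint model")
        if prev_state is not None:
            transferred, skipped = nn.transfer_parameters(prev_state, model)
            if not transferred:
                raise ValueError("transfer mismatch: no compatible parameters between rungs")
            transfer_logs.append({"transferred": transferred, "skipped": skipped})
        model, hist = train(model, tr, va, train_cfg)
        histories.append(hist)
        prev_state = nn.state_dict(model)
    return model, histories, transfer_logs
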