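"""Supervised training of the U-net on paired (input, target) cubes.

Optimization follows the restoration recipe: stochastic gradient descent
with batches of 8 cubes, mean-absolute-error loss, initial learning rate
1e-3 halved whenever the validation loss fails to improve for 5 consecutive
epochs.  Data augmentation applies random axis-aligned cube rotations (to
input and target identically), plus Gaussian blurring and noise-patch
corruption of the input only — the target is the clean supervision signal
and is never degraded.

Every run is fully reproducible from its seed: shuffling, augmentation and
weight initialization all derive from it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage

from .layers import SGD
from .unet3d import UNetModel

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "TrainHistory",
    "PlateauScheduler",
    "augment_pair",
    "mae_loss",
    "train",
]


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    """Augmentation probabilities and parameters (per training pair)."""

    rotation_prob: float = 0.3
    blur_prob: float = 0.3
    blur_sigma_range: tuple[float, float] = (0.3, 1.5)
    corrupt_prob: float = 0.3
    corrupt_patch_size: int = 16
    corrupt_noise_std: float = 0.1

    def __post_init__(self) -> None:
        for p in (self.rotation_prob, self.blur_prob, self.corrupt_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(self.blur_sigma_range) < 0:
            raise ValueError("blur sigma must be nonnegative")
        if self.corrupt_patch_size < 1:
            raise ValueError("corrupt patch size must be >= 1")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 5
    max_epochs: int = 25
    early_stop_patience: int | None = None
    momentum: float = 0.0
    #: optional global-norm gradient clipping; MAE gradients are bounded by
    #: construction, so this is off by default.
    clip_norm: float | None = None
    min_rel_improvement: float = 1e-5
    seed: int = 0
    augment: AugmentConfig | None = dataclasses.field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if self.batch_size < 1 or self.lr_patience < 1:
            raise ValueError("batch_size and lr_patience must be >= 1")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch record of a training run."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    learning_rate: list[float] = dataclasses.field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.learning_rate,
            }
        )


class PlateauScheduler:
    """Halve the learning rate when validation loss plateaus.

    "Improvement" means strictly better than the best seen so far by at
    least ``min_rel_improvement`` relative; the patience counter resets on
    improvement and after each decay.
    """

    def __init__(
        self,
        initial_lr: float,
        factor: float = 0.5,
        patience: int = 5,
        min_rel_improvement: float = 1e-5,
    ):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_rel = min_rel_improvement
        self.best = np.inf
        self.counter = 0

    def step(self, val_loss: float) -> float:
        """Record an epoch's validation loss; return the LR for the next epoch."""
        if val_loss < self.best * (1.0 - self.min_rel):
            self.best = val_loss
            self.counter = 0
        else:
            self.counter += 1
            if self.counter >= self.patience:
                self.lr *= self.factor
                self.counter = 0
        return self.lr


_ROTATIONS = [
    (k, axes)
    for axes in ((0, 1), (0, 2), (1, 2))
    for k in (1, 2, 3)
]


def _random_orientation(cube: np.ndarray, ops: list[tuple[int, tuple[int, int]]]) -> np.ndarray:
    out = cube
    for k, axes in ops:
        out = np.rot90(out, k, axes)
    return out


def random_rotation_ops(rng: np.random.Generator) -> list[tuple[int, tuple[int, int]]]:
    """One of the 24 axis-aligned cube orientations, as a list of rot90 ops.

    Sampled as a uniform z-face choice (6) times an in-plane spin (4), which
    enumerates the full octahedral rotation group.
    """
    face = rng.integers(6)
    spin = rng.integers(4)
    ops: list[tuple[int, tuple[int, int]]] = []
    # move one of the 6 axis directions to +z
    face_ops = [
        [],
        [(2, (0, 1))],
        [(1, (0, 1))],
        [(3, (0, 1))],
        [(1, (0, 2))],
        [(3, (0, 2))],
    ]
    ops.extend(face_ops[face])
    if spin:
        ops.append((int(spin), (1, 2)))
    return ops


def augment_pair(
    input_cube: np.ndarray,
    target_cube: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastically augment a training pair (see module docstring)."""
    if input_cube.shape != target_cube.shape:
        raise ValueError(f"shape mismatch: {input_cube.shape} vs {target_cube.shape}")
    inp, tgt = input_cube, target_cube
    if rng.random() < config.rotation_prob:
        ops = random_rotation_ops(rng)
        inp = _random_orientation(inp, ops)
        tgt = _random_orientation(tgt, ops)
    if rng.random() < config.blur_prob:
        lo, hi = config.blur_sigma_range
        sigma = float(rng.uniform(lo, hi))
        inp = scipy.ndimage.gaussian_filter(inp, sigma)
    if rng.random() < config.corrupt_prob:
        ps = min(config.corrupt_patch_size, min(inp.shape))
        corner = [int(rng.integers(0, s - ps + 1)) for s in inp.shape]
        inp = np.array(inp, copy=True)
        sl = tuple(slice(c, c + ps) for c in corner)
        inp[sl] = rng.normal(0.0, config.corrupt_noise_std, size=(ps, ps, ps)).astype(inp.dtype)
    return np.ascontiguousarray(inp), np.ascontiguousarray(tgt)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute error over all voxels and batch entries."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def _epoch_val_loss(model: UNetModel, val_pairs, batch_size: int) -> float:
    inputs, targets = val_pairs
    losses = []
    for i in range(0, len(inputs), batch_size):
        pred = model.forward(inputs[i : i + batch_size])
        losses.append(np.sum(np.abs(pred - targets[i : i + batch_size])))
    total_vox = sum(np.prod(t.shape) for t in targets)
    return float(np.sum(losses) / total_vox)


def _as_arrays(pairs):
    if isinstance(pairs, tuple) and len(pairs) == 2:
        return np.asarray(pairs[0], np.float32), np.asarray(pairs[1], np.float32)
    inputs = np.stack([p[0] for p in pairs]).astype(np.float32)
    targets = np.stack([p[1] for p in pairs]).astype(np.float32)
    return inputs, targets


def train(
    model: UNetModel,
    train_pairs,
    val_pairs,
    config: TrainConfig,
    *,
    callback=None,
) -> tuple[UNetModel, TrainHistory]:
    """Train ``model`` in place; returns it with its best-validation weights.

    ``train_pairs`` / ``val_pairs`` are either ``(inputs, targets)`` stacked
    arrays of shape (N, D, H, W) or sequences of (input, target) cube pairs.
    """
    tr_in, tr_tg = _as_arrays(train_pairs)
    va = _as_arrays(val_pairs)
    if len(tr_in) == 0 or len(va[0]) == 0:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(config.seed)
    model.validate_weights()
    opt = SGD(model.layers(), config.initial_lr, config.momentum, config.clip_norm)
    sched = PlateauScheduler(
        config.initial_lr, config.lr_decay_factor, config.lr_patience, config.min_rel_improvement
    )
    history = TrainHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(tr_in))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment is not None:
                batch = [augment_pair(tr_in[i], tr_tg[i], config.augment, rng) for i in idx]
                bi = np.stack([b[0] for b in batch])
                bt = np.stack([b[1] for b in batch])
            else:
                bi, bt = tr_in[idx], tr_tg[idx]
            pred = model.forward(bi)
            loss = mae_loss(pred, bt)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
            opt.zero_grad()
            model.backward(np.sign(pred - bt) / pred.size)
            opt.step()
            epoch_losses.append(loss)
        val_loss = _epoch_val_loss(model, va, config.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.learning_rate.append(opt.lr)
        if val_loss < best_val * (1.0 - config.min_rel_improvement):
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        opt.lr = sched.step(val_loss)
        if callback is not None:
            callback(epoch, history)
        if (
            config.early_stop_patience is not None
            and epochs_since_best >= config.early_stop_patience
        ):
            break
    model.set_weights(best_weights)
    return model, history
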