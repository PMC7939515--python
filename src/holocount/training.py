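"""Loss, optimization recipe and model-selection harness.

The training objective is the sum of a soft-Dice term and a binary
cross-entropy term between the network's probability map ``p`` and the binary
ground truth ``y``::

    L = (1 - (2*sum(y*p) + eps) / (sum(y) + sum(p) + eps))
        - (1/N) * sum(y*log(p) + (1-y)*log(1-p))

with a small smoothing constant in the Dice ratio (empty-foreground stability)
and probabilities clamped inside the logarithms.  Optimization is SGD with
momentum 0.9, initial learning rate 0.01 decayed by 10x every 30 epochs, L2
weight decay 1e-4, batch size 4, 60 epochs — with augmentation on training
batches only and per-epoch validation Dice at threshold 0.5.  The returned
model is the checkpoint with the best validation Dice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import counting, metrics
from .data_pipeline import AugmentSpec, NormStats, augment, compute_norm_stats, normalize, split_folds
from .fcn_model import ModelConfig, UNet, build_model
from .sim_dhm import SimConfig

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "lr_at",
    "dice_loss",
    "bce_loss",
    "combined_loss",
    "combined_loss_grad",
    "SGDMomentum",
    "train",
    "grid_search",
    "cross_validate",
    "desk_profile",
]

DICE_SMOOTH = 1e-6
LOG_CLAMP = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe; defaults are the full-scale settings."""

    batch_size: int = 4
    momentum: float = 0.9
    lr0: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 30
    weight_decay: float = 1e-4
    epochs: int = 60
    seed: int = 0
    threshold: float = 0.5
    scale_profile: str = "full"

    def __post_init__(self) -> None:
        if min(self.batch_size, self.lr0, self.lr_decay_factor, self.lr_decay_every, self.epochs) <= 0:
            raise ValueError("batch_size, lr0, decay factor/interval and epochs must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: lr0 / factor**floor(epoch / every)."""
    return cfg.lr0 / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def _check_pair(prob: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"probability shape {prob.shape} != truth shape {truth.shape}")
    return prob, truth


def dice_loss(prob: np.ndarray, truth: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft-Dice term: 1 - (2*sum(y*p)+s) / (sum(y)+sum(p)+s)."""
    prob, truth = _check_pair(prob, truth)
    num = 2.0 * float((truth * prob).sum()) + smooth
    den = float(truth.sum()) + float(prob.sum()) + smooth
    return 1.0 - num / den


def bce_loss(prob: np.ndarray, truth: np.ndarray, clamp: float = LOG_CLAMP) -> float:
    """Pixel-mean binary cross entropy with probabilities clamped to
    [clamp, 1-clamp] inside the logarithms."""
    prob, truth = _check_pair(prob, truth)
    p = np.clip(prob, clamp, 1.0 - clamp)
    return float(-(truth * np.log(p) + (1.0 - truth) * np.log1p(-p)).mean())


def combined_loss(prob: np.ndarray, truth: np.ndarray) -> float:
    """Soft-Dice plus cross entropy for one probability/truth pair."""
    return dice_loss(prob, truth) + bce_loss(prob, truth)


def combined_loss_grad(prob: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Analytic dL/dprob of :func:`combined_loss` (same shape as ``prob``)."""
    prob, truth = _check_pair(prob, truth)
    num = 2.0 * (truth * prob).sum() + DICE_SMOOTH
    den = truth.sum() + prob.sum() + DICE_SMOOTH
    ddice = -(2.0 * truth * den - num) / den**2
    p = np.clip(prob, LOG_CLAMP, 1.0 - LOG_CLAMP)
    dbce = -(truth / p - (1.0 - truth) / (1.0 - p)) / prob.size
    return ddice + dbce


class SGDMomentum:
    """SGD with a momentum buffer over (gradient + weight_decay * param),
    the convention of mainstream deep-learning frameworks."""

    def __init__(self, model: UNet, momentum: float, weight_decay: float):
        self.model = model
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p) for p in model.parameters()]

    def step(self, lr: float) -> None:
        i = 0
        for layer in self.model.param_layers():
            for attr, grad_attr in layer.params():
                p = getattr(layer, attr)
                g = getattr(layer, grad_attr).astype(p.dtype) + self.weight_decay * p
                v = self._velocity[i]
                v *= self.momentum
                v += g
                p -= (lr * v).astype(p.dtype)
                i += 1


def _batch_dsc(pred_mask: np.ndarray, truth: np.ndarray) -> float:
    c = metrics.confusion(pred_mask, truth)
    return metrics.dsc(c)


def _validate(
    model: UNet, val_set, stats: NormStats, threshold: float, batch_size: int
) -> tuple[float, float]:
    losses, dscs = [], []
    for img, mask in val_set:
        prob = model.forward(normalize(img, stats)[None, None], train=False)[0, 0]
        losses.append(combined_loss(prob, mask))
        dscs.append(_batch_dsc(prob > threshold, mask.astype(bool)))
    return float(np.mean(losses)), float(np.mean(dscs))


def train(
    model: UNet,
    train_set: list[tuple[np.ndarray, np.ndarray]],
    val_set: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    augment_spec: AugmentSpec | None = AugmentSpec(),
    norm_stats: NormStats | None = None,
    log=None,
) -> tuple[UNet, pd.DataFrame]:
    """Train with the configured recipe; return (best model, learning curve).

    ``train_set``/``val_set`` are lists of (hologram, binary mask) pairs whose
    sides must already be divisible by the model's size divisor.
    Normalization stats are pooled from the training holograms unless given.
    Augmentation is applied to training batches only.  The model returned
    carries the parameters of the epoch with the best validation Dice, which
    by construction is >= the final-epoch validation Dice.  Runs are
    deterministic for a fixed (cfg.seed, model) on a single thread.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    stats = norm_stats or compute_norm_stats([img for img, _ in train_set])
    rng = np.random.default_rng(cfg.seed)
    opt = SGDMomentum(model, cfg.momentum, cfg.weight_decay)
    records = []
    best_dsc = -1.0
    best_params = [p.copy() for p in model.parameters()]
    n = len(train_set)
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = rng.permutation(n)
        epoch_losses, epoch_dscs = [], []
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            imgs, masks = [], []
            for i in idx:
                img, mask = train_set[int(i)]
                if augment_spec is not None:
                    img, mask = augment(img, mask, augment_spec, rng)
                imgs.append(normalize(img, stats))
                masks.append(np.asarray(mask, dtype=np.float64))
            x = np.stack(imgs)[:, None]
            y = np.stack(masks)[:, None]
            prob = model.forward(x, train=True)
            batch_losses = [combined_loss(prob[j, 0], y[j, 0]) for j in range(len(idx))]
            loss = float(np.mean(batch_losses))
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}"
                )
            dprob = np.stack(
                [combined_loss_grad(prob[j, 0], y[j, 0]) for j in range(len(idx))]
            )[:, None] / len(idx)
            model.backward(dprob)
            opt.step(lr)
            epoch_losses.append(loss)
            epoch_dscs.append(_batch_dsc(prob > cfg.threshold, y.astype(bool)))
        val_loss, val_dsc = _validate(model, val_set, stats, cfg.threshold, cfg.batch_size)
        records.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "train_dsc": float(np.mean(epoch_dscs)),
                "val_loss": val_loss,
                "val_dsc": val_dsc,
            }
        )
        if log is not None:
            log(records[-1])
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_params = [p.copy() for p in model.parameters()]
    model.set_parameters(best_params)
    model.norm_stats = stats
    return model, pd.DataFrame(records)


def grid_search(
    lr_grid: list[float],
    wd_grid: list[float],
    train_set,
    val_set,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    seed: int = 0,
    augment_spec: AugmentSpec | None = AugmentSpec(),
) -> tuple[float, float, pd.DataFrame]:
    """Train one model per (learning rate, weight decay) pair.

    Returns the argmax pair and a table of best-epoch validation Dice values
    (rows: weight decay, columns: learning rate).  Hyper-parameter search is
    meant to run on the first cross-validation round only; the remaining
    rounds reuse the tuned pair.  A diverged cell is recorded as NaN and the
    search continues.
    """
    if not lr_grid or not wd_grid:
        raise ValueError("grids must be non-empty")
    table = pd.DataFrame(index=list(wd_grid), columns=list(lr_grid), dtype=float)
    table.index.name = "weight_decay"
    table.columns.name = "learning_rate"
    best = (None, None, -np.inf)
    for wd in wd_grid:
        for lr in lr_grid:
            run_cfg = replace(cfg, lr0=lr, weight_decay=wd)
            model = build_model(model_cfg, seed=seed)
            try:
                _, curve = train(model, train_set, val_set, run_cfg, augment_spec)
                score = float(curve["val_dsc"].max())
            except TrainingDivergedError:
                score = float("nan")
            table.loc[wd, lr] = score
            if math.isfinite(score) and score > best[2]:
                best = (lr, wd, score)
    if best[0] is None:
        raise TrainingDivergedError("every grid cell diverged")
    return best[0], best[1], table


def cross_validate(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    k: int,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    post_cfg: counting.PostprocessConfig | None = None,
    augment_spec: AugmentSpec | None = AugmentSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-fold cross validation of the full train->predict->count pipeline.

    Trains ``k`` models, evaluates each on its held-out fold, and returns
    (per-fold table, mean/std summary over folds).
    """
    post_cfg = post_cfg or counting.PostprocessConfig(threshold=cfg.threshold)
    folds = split_folds(list(range(len(dataset))), k, seed=seed)
    rows = []
    for fold in range(k):
        train_ids = folds.train_ids(fold)
        test_ids = folds.fold_ids(fold)
        model = build_model(model_cfg, seed=seed + fold)
        model, _ = train(
            model,
            [dataset[i] for i in train_ids],
            [dataset[i] for i in test_ids],
            cfg,
            augment_spec,
        )
        stats = model.norm_stats
        probs = [
            model.forward(normalize(dataset[i][0], stats)[None, None], train=False)[0, 0]
            for i in test_ids
        ]
        _, summary = metrics.evaluate_set(probs, [dataset[i][1] for i in test_ids], post_cfg)
        row = {"fold": fold, "n_test": len(test_ids)}
        row.update({k_: v["mean"] for k_, v in summary.items()})
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    agg = per_fold.drop(columns=["n_test"]).agg(["mean", "std"])
    return per_fold, agg


def desk_profile(seed: int = 0) -> dict:
    """Desk-scale study conditions: 128x128 scenes with 5-15 cells of 5-8 px
    taper radius, a depth-4 / 16-channel model, and 10 epochs of the standard
    optimization recipe.  Keeps single-CPU training to a few minutes.

    The desk profile trains without augmentation (``augment=None``): train and
    test images come from the same simulator distribution, so a 10-epoch run
    cannot overfit in the way augmentation guards against at full scale, and
    the broadened input distribution would only slow convergence within the
    short budget.
    """
    return {
        "sim": SimConfig(
            image_size=(128, 128),
            n_cells_range=(5, 15),
            cell_radius_range=(5.0, 8.0),
            seed=seed,
        ),
        "model": ModelConfig(depth=4, base_channels=16),
        "train": TrainConfig(epochs=10, seed=seed, scale_profile="desk"),
        "augment": None,
    }
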