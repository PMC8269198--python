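"""Training loop: Adam, plateau learning-rate decay, divergence early stop.

The optimizer schedule follows the study design: Adam at learning rate 1e-4,
halved whenever the training loss fails to improve for 15 consecutive
optimizer steps.  Training runs on randomly augmented square patches and
stops when the validation loss diverges from its best value (exceeds it by a
configurable margin for a configurable number of consecutive checks) or when
``max_iters`` is reached; the weights returned are those of the best
validation checkpoint.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, Sample, augment, sample_patch
from .losses import DiscriminativeLossParams, assemble_loss
from .models import NetworkOutput, _SegModel
from .nn import Adam, Tensor
from .weight_maps import compute_weight_map

__all__ = ["TrainConfig", "PlateauState", "lr_schedule_step", "train",
           "TrainingLog"]


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run."""

    strategy: str = "vanilla"
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.5
    plateau_patience_iters: int = 15
    plateau_rel_tol: float = 1e-4
    plateau_warmup_iters: int = 100  # detector off while the loss reorganizes
    plateau_cooldown_iters: int = 75  # detector off after each lr reduction
    batch_size: int = 8
    loss_smoothing: float = 0.998  # EMA factor for the plateau detector; 0 = raw
    max_iters: int = 500
    patch_size: int = 224
    val_interval: int = 25
    early_stop_margin: float = 0.05
    early_stop_patience: int = 10
    seed: int = 0
    augmentation: Optional[AugmentationConfig] = field(
        default_factory=AugmentationConfig)
    disc_params: DiscriminativeLossParams = field(
        default_factory=DiscriminativeLossParams)
    disc_weight: float = 1.0
    weight_map_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.plateau_patience_iters < 1:
            raise ValueError("plateau_patience_iters must be >= 1")


@dataclass
class PlateauState:
    """State of the plateau learning-rate schedule."""

    lr: float
    best_loss: float = np.inf
    stall_count: int = 0
    patience: int = 15
    factor: float = 0.5
    rel_tol: float = 1e-4


def lr_schedule_step(state: PlateauState, current_loss: float) -> PlateauState:
    """Advance the plateau detector by one optimizer step.

    An improvement is a loss below ``best·(1 − rel_tol)``; after ``patience``
    consecutive non-improving steps the learning rate is multiplied by
    ``factor`` and the counter resets.  The lr sequence is non-increasing.
    """
    s = replace(state)
    if current_loss < s.best_loss * (1.0 - s.rel_tol) or not np.isfinite(s.best_loss):
        s.best_loss = min(current_loss, s.best_loss)
        s.stall_count = 0
        return s
    s.stall_count += 1
    if s.stall_count >= s.patience:
        s.lr *= s.factor
        s.stall_count = 0
    return s


@dataclass
class TrainingLog:
    rows: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.rows.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _image_chw(image: np.ndarray) -> np.ndarray:
    img = image.astype(np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    return np.moveaxis(img, -1, 0)


def _make_batch(samples: Sequence[Sample], cfg: TrainConfig,
                rng: np.random.Generator):
    """Random augmented patches: images (N,3,P,P), labels (N,P,P), weights."""
    idx = rng.integers(0, len(samples), size=cfg.batch_size)
    imgs, labs, wts = [], [], []
    for i in idx:
        s = samples[int(i)]
        if cfg.augmentation is not None:
            s = augment(s, cfg.augmentation, rng)
        p = sample_patch(s, size=cfg.patch_size, rng=rng)
        imgs.append(_image_chw(p.image))
        labs.append(p.truth)
        if cfg.strategy == "weighted":
            wm = p.weight_map
            if wm is None:
                # geometry changed by augmentation/cropping: rebuild so the
                # 10-px gap rule holds in the patch frame
                wm = compute_weight_map(p.truth, **cfg.weight_map_kwargs)
            wts.append(wm)
    return (np.stack(imgs), np.stack(labs).astype(np.int32),
            wts if cfg.strategy == "weighted" else None)


def _evaluate_loss(model: _SegModel, patches, cfg: TrainConfig) -> float:
    model.eval()
    total = 0.0
    for imgs, labs, wts in patches:
        out = model(Tensor(imgs))
        loss = assemble_loss(cfg.strategy, out, labs, weight_maps=wts,
                             disc_params=cfg.disc_params,
                             disc_weight=cfg.disc_weight)
        total += loss.item()
    model.train()
    return total / max(len(patches), 1)


def train(model: _SegModel, train_set: Sequence[Sample],
          val_set: Sequence[Sample], config: TrainConfig
          ) -> tuple[_SegModel, TrainingLog]:
    """Fit ``model``; returns it loaded with the best-validation weights.

    Deterministic given ``config.seed``: two runs with identical seeds
    produce identical training-loss sequences.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    sched = PlateauState(lr=config.learning_rate,
                         patience=config.plateau_patience_iters,
                         factor=config.lr_decay_factor,
                         rel_tol=config.plateau_rel_tol)
    log = TrainingLog()

    # fixed validation patches (deterministic, no augmentation)
    val_rng = np.random.default_rng(config.seed + 1)
    val_cfg = replace(config, augmentation=None)
    val_patches = []
    for s in val_set:
        p = sample_patch(s, size=config.patch_size, rng=val_rng)
        wts = None
        if config.strategy == "weighted":
            wm = p.weight_map if p.weight_map is not None else \
                compute_weight_map(p.truth, **config.weight_map_kwargs)
            wts = [wm]
        val_patches.append((_image_chw(p.image)[None],
                            p.truth.astype(np.int32)[None], wts))

    best_val = np.inf
    best_state = copy.deepcopy(model.named_state())
    stop_count = 0
    val_loss = np.nan
    # the plateau detector watches a smoothed loss: with small stochastic
    # batches the raw loss is noisy enough that its running minimum is
    # essentially never beaten, which would halve the lr on schedule noise
    ema = None
    detector_quiet_until = config.plateau_warmup_iters

    for it in range(1, config.max_iters + 1):
        imgs, labs, wts = _make_batch(train_set, config, rng)
        out = model(Tensor(imgs))
        loss = assemble_loss(config.strategy, out, labs, weight_maps=wts,
                             disc_params=config.disc_params,
                             disc_weight=config.disc_weight)
        loss_val = loss.item()
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at iteration {it}: {loss_val}")
        model.zero_grad()
        loss.backward()
        opt.lr = sched.lr
        opt.step()
        beta = config.loss_smoothing
        ema = loss_val if ema is None else beta * ema + (1 - beta) * loss_val
        if it > detector_quiet_until:
            prev_lr = sched.lr
            sched = lr_schedule_step(sched, ema)
            if sched.lr < prev_lr:
                # cooldown + re-baseline: with stochastic batches the running
                # best is otherwise set by a noise dip and every subsequent
                # window stalls, cascading the lr to zero
                detector_quiet_until = it + config.plateau_cooldown_iters
                sched.best_loss = ema

        stop = False
        if it % config.val_interval == 0 or it == config.max_iters:
            val_loss = _evaluate_loss(model, val_patches, val_cfg)
            if val_loss < best_val:
                best_val = val_loss
                best_state = copy.deepcopy(model.named_state())
            if val_loss > best_val * (1.0 + config.early_stop_margin):
                stop_count += 1
            else:
                stop_count = 0
            stop = stop_count >= config.early_stop_patience
        log.append(iteration=it, train_loss=loss_val, val_loss=val_loss,
                   lr=sched.lr)
        if stop:
            break

    model.load_state(best_state)
    return model, log
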