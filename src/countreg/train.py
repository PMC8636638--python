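"""Two-phase training protocol with discriminative LRs and a one-cycle schedule.

Phase one trains only the regression head while the convolutional trunk
stays frozen; phase two unfreezes everything and fine-tunes with
discriminative learning rates (small for early layers, larger towards the
head).  Within each phase the learning rate follows a one-cycle trajectory:
warm up to a single maximum, then anneal below the starting value.  The
model returned from a phase is the checkpoint with the minimum validation
loss over its epochs ("best epoch"), evaluated on un-augmented images.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field

import numpy as np

from .data import AugmentationPolicy, CountDataset, augment
from .model import CountRegressor, HuberLossSpec, huber_loss, huber_loss_grad
from .nn import Adam

__all__ = [
    "OneCycleSpec",
    "PhaseSpec",
    "TrainConfig",
    "one_cycle_lr",
    "train_phase",
    "run_protocol",
    "otolith_protocol",
    "seal_protocol",
    "desk_protocol",
]


@dataclass(frozen=True)
class OneCycleSpec:
    """One-cycle schedule: cosine warm-up to a peak, cosine anneal below start."""

    max_lr_multiplier: float = 10.0
    warmup_fraction: float = 0.3
    start_dampening: float = 10.0  # start at base/start_dampening
    end_dampening: float = 100.0  # end at base/end_dampening

    def __post_init__(self):
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.max_lr_multiplier < 1.0 or self.start_dampening < 1.0:
            raise ValueError("schedule must start below its peak")
        if self.end_dampening < self.start_dampening:
            raise ValueError("schedule must end at or below its start value")


@dataclass(frozen=True)
class PhaseSpec:
    """One training phase: epochs, per-section LRs, frozen sections, schedule.

    ``section_lrs`` is (early trunk, late trunk, head), nondecreasing — the
    discriminative-LR convention.  The head section can never be frozen.
    """

    epochs: int
    section_lrs: tuple[float, float, float]
    frozen_sections: frozenset = frozenset()
    cycle: OneCycleSpec = OneCycleSpec()

    def __post_init__(self):
        a, b, c = self.section_lrs
        if not a <= b <= c:
            raise ValueError("section_lrs must be nondecreasing (early <= late <= head)")
        if not frozenset(self.frozen_sections) <= {1, 2}:
            raise ValueError("only trunk sections 1 and 2 may be frozen")
        object.__setattr__(self, "frozen_sections", frozenset(self.frozen_sections))


@dataclass
class TrainConfig:
    batch_size: int = 84
    seed: int = 0
    loss: HuberLossSpec = field(default_factory=HuberLossSpec)
    augmentation: AugmentationPolicy | None = None
    log: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def one_cycle_lr(step: int, total_steps: int, base_lr: float, cycle: OneCycleSpec) -> float:
    """Learning rate at ``step`` of a ``total_steps``-long one-cycle schedule."""
    if total_steps <= 0:
        raise ValueError("total_steps must be > 0")
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    if total_steps == 1:
        return base_lr * cycle.max_lr_multiplier
    peak = base_lr * cycle.max_lr_multiplier
    start = base_lr / cycle.start_dampening
    end = base_lr / cycle.end_dampening
    warm_steps = max(1, int(round(cycle.warmup_fraction * (total_steps - 1))))
    if step <= warm_steps:
        t = step / warm_steps
        return start + (peak - start) * 0.5 * (1 - math.cos(math.pi * t))
    t = (step - warm_steps) / (total_steps - 1 - warm_steps)
    return end + (peak - end) * 0.5 * (1 + math.cos(math.pi * t))


def _validation_loss(model: CountRegressor, val_set: CountDataset, config: TrainConfig) -> float:
    preds = model.predict(val_set.items, batch_size=config.batch_size)
    return huber_loss(preds, val_set.labels, threshold=config.loss.threshold)


def train_phase(
    model: CountRegressor,
    train_set: CountDataset,
    val_set: CountDataset,
    phase: PhaseSpec,
    config: TrainConfig,
) -> tuple[CountRegressor, list[dict]]:
    """Run one phase; returns the best-validation-epoch model and its history.

    Frozen sections are bit-identical before and after.  History rows hold
    ``epoch`` (1-based), ``train_loss``, ``val_loss`` and the head LR at the
    last step of the epoch.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if phase.epochs == 0:
        return model, []

    sections = model.sections
    trainable = [s for s in (1, 2, 3) if s not in phase.frozen_sections]
    groups = [
        {"layers": sections[s], "lr": phase.section_lrs[s - 1]} for s in trainable
    ]
    opt = Adam(groups)
    # backward pass can stop above the deepest trainable backbone layer
    if 1 in trainable:
        stop_at = 0
    elif 2 in trainable:
        stop_at = model.section_split
    else:
        stop_at = None  # head-only: no backbone backward at all

    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    n_batches = max(1, math.ceil(n / config.batch_size))
    total_steps = phase.epochs * n_batches

    history: list[dict] = []
    best_val = math.inf
    best_state = None
    step = 0
    for epoch in range(1, phase.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        lr_scale = 1.0
        for bi in range(n_batches):
            idx = order[bi * config.batch_size : (bi + 1) * config.batch_size]
            images = [train_set[int(i)] for i in idx]
            if config.augmentation is not None:
                images = [augment(im, config.augmentation, rng) for im in images]
            batch = model.prepare_batch(images)
            targets = np.array([train_set[int(i)].label for i in idx], dtype=np.float64)

            # frozen trunk sections need no activation caches or backward pass
            feats = model.backbone.forward(batch, train=stop_at is not None)
            preds = model.head.forward(feats, train=True).ravel()
            loss = huber_loss(preds, targets, threshold=config.loss.threshold)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            epoch_losses.append(loss)

            opt.zero_grad()
            dpred = huber_loss_grad(preds, targets, threshold=config.loss.threshold)
            dfeat = model.head.backward(dpred[:, None].astype(np.float32))
            if stop_at is not None:
                model.backbone.backward(dfeat, stop_at=stop_at)
            lr_scale = one_cycle_lr(step, total_steps, 1.0, phase.cycle)
            opt.step(lr_scale=lr_scale)
            step += 1

        val_loss = _validation_loss(model, val_set, config)
        if not math.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr_head": phase.section_lrs[2] * lr_scale,
        }
        history.append(row)
        if config.log:
            print(
                f"epoch {epoch:3d}  train {row['train_loss']:.4f}  val {val_loss:.4f}",
                file=sys.stderr,
            )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.copy_state()

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def run_protocol(
    model: CountRegressor,
    train_set: CountDataset,
    val_set: CountDataset,
    head_phase: PhaseSpec,
    finetune_phase: PhaseSpec,
    config: TrainConfig,
) -> tuple[CountRegressor, dict[str, list[dict]]]:
    """Head-only phase then full fine-tune, each with best-epoch checkpointing.

    Before the head phase the (zero-initialised) output bias is set to the
    training-label mean, so the bounded Huber gradient does not have to walk
    the output from 0 to the label scale.
    """
    if head_phase.epochs > 0 or finetune_phase.epochs > 0:
        out_layer = model.head.layers[-1]
        if np.all(out_layer.params["W"] == 0) and np.all(out_layer.params["b"] == 0):
            out_layer.params["b"][...] = float(train_set.labels.mean())
    model, head_hist = train_phase(model, train_set, val_set, head_phase, config)
    model, ft_hist = train_phase(model, train_set, val_set, finetune_phase, config)
    return model, {"head": head_hist, "finetune": ft_hist}


def _discriminative(lo: float, hi: float) -> tuple[float, float, float]:
    """Three-section LRs from a stated range: endpoints plus geometric mean."""
    return (lo, math.sqrt(lo * hi), hi)


def otolith_protocol() -> tuple[PhaseSpec, PhaseSpec, TrainConfig]:
    """Ring-style configuration: head 25 epochs at LR 5e-2 (trunk frozen),
    then 50 epochs of full fine-tuning with discriminative LR 9e-7..9e-5;
    batch size 84."""
    head = PhaseSpec(epochs=25, section_lrs=(5e-2, 5e-2, 5e-2), frozen_sections={1, 2})
    finetune = PhaseSpec(epochs=50, section_lrs=_discriminative(9e-7, 9e-5))
    return head, finetune, TrainConfig(batch_size=84)


def seal_protocol() -> tuple[PhaseSpec, PhaseSpec, TrainConfig]:
    """Dot-style configuration: head 50 epochs at LR 3e-2 (trunk frozen),
    then 50 epochs of full fine-tuning with discriminative LR 3e-4..3e-2;
    batch size 100."""
    head = PhaseSpec(epochs=50, section_lrs=(3e-2, 3e-2, 3e-2), frozen_sections={1, 2})
    finetune = PhaseSpec(epochs=50, section_lrs=_discriminative(3e-4, 3e-2))
    return head, finetune, TrainConfig(batch_size=100)


def desk_protocol(
    head_epochs: int = 10,
    finetune_epochs: int = 12,
    batch_size: int = 50,
    seed: int = 0,
    augmentation: AugmentationPolicy | None = None,
) -> tuple[PhaseSpec, PhaseSpec, TrainConfig]:
    """CPU desk-scale protocol for the tiny backbone on 64x64 scenes.

    Same structure as the full protocols (frozen head phase, then
    discriminative full fine-tune with one-cycle), with epoch counts and
    LRs sized for minutes-scale training from random initialisation.
    """
    if augmentation is None:
        augmentation = AugmentationPolicy(
            lighting_jitter_range=(0.9, 1.1), max_zoom_fraction=0.0
        )
    head = PhaseSpec(epochs=head_epochs, section_lrs=(3e-3, 3e-3, 3e-3), frozen_sections={1, 2})
    finetune = PhaseSpec(epochs=finetune_epochs, section_lrs=_discriminative(3e-4, 3e-3))
    return head, finetune, TrainConfig(batch_size=batch_size, seed=seed, augmentation=augmentation)
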