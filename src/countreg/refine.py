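"""Two-step noisy-label refinement.

A model trained on a clean subset is used to predict counts on the noisy
pool; images are ranked by signed discrepancy (prediction minus noisy
label).  The K most over-estimated and K most under-estimated images are
relabelled by an oracle (the ground-truth recount); any image the oracle
cannot identify is discarded and replaced by the next-worst image *in the
same tail*.  The relabelled selection then supplements the clean subset and
the whole model is fine-tuned on a fresh 80/20 split.

Residuals are computed against the noisy label deliberately — a large
positive residual flags an image whose label probably under-counts, which
is exactly where relabelling buys the most.  Raw (unrounded) predictions
are used for ranking, since rounding would create mass ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import CountDataset, LabelledImage, train_val_split
from .model import CountRegressor
from .synthetic import UNIDENTIFIABLE, oracle_relabel
from .train import PhaseSpec, TrainConfig, train_phase, _discriminative

__all__ = [
    "DiscrepancyRecord",
    "RefinementConfig",
    "rank_discrepancies",
    "select_refinement_set",
    "refine",
]


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Per-image ranking record: noisy label, raw prediction, signed residual."""

    id: str
    noisy_label: int
    predicted_count: float
    image: LabelledImage = field(repr=False, compare=False)

    @property
    def residual(self) -> float:
        return self.predicted_count - self.noisy_label


def default_refinement_phase() -> PhaseSpec:
    """Fine-tune 50 epochs, all sections, discriminative LR 1e-5..1e-3."""
    return PhaseSpec(epochs=50, section_lrs=_discriminative(1e-5, 1e-3))


@dataclass
class RefinementConfig:
    k_over: int = 50
    k_under: int = 50
    finetune_phase: PhaseSpec = field(default_factory=default_refinement_phase)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    train_fraction: float = 0.8

    def __post_init__(self):
        if self.k_over < 0 or self.k_under < 0:
            raise ValueError("k_over and k_under must be >= 0")


def rank_discrepancies(
    model: CountRegressor, noisy_pool: CountDataset, batch_size: int = 128
) -> list[DiscrepancyRecord]:
    """One record per pool image, sorted by residual descending, ties by id.

    The head of the list holds the most over-estimated images (prediction far
    above the noisy label), the tail the most under-estimated.
    """
    if len(noisy_pool) == 0:
        raise ValueError("noisy pool is empty")
    preds = model.predict(noisy_pool.items, batch_size=batch_size)
    records = [
        DiscrepancyRecord(id=im.id, noisy_label=int(im.label), predicted_count=float(p), image=im)
        for im, p in zip(noisy_pool, preds)
    ]
    return sorted(records, key=lambda r: (-r.residual, r.id))


def select_refinement_set(
    records: list[DiscrepancyRecord],
    config: RefinementConfig,
    oracle=oracle_relabel,
) -> tuple[CountDataset, list[dict]]:
    """Pick the k_over/k_under tail images, relabelled by the oracle.

    Walks each tail inward; an unidentifiable image is discarded and the next
    record in the same tail takes its place.  Selected images carry the
    oracle label and lose their noisy flag.  The selection report has one
    row per *selected* image; ``replaced_flag`` marks images that filled a
    slot only because an earlier image in their tail was discarded.

    When ``k_over + k_under`` covers the whole pool the selection is simply
    every identifiable image, with no duplicates.  A tail that runs out of
    replacement candidates before reaching its quota (and not because the
    quotas cover the pool) is an error.
    """
    report: list[dict] = []
    chosen: dict[str, LabelledImage] = {}
    whole_pool = config.k_over + config.k_under >= len(records)

    def walk(tail: list[DiscrepancyRecord], k: int, name: str) -> None:
        taken = 0
        walked = 0
        for rec in tail:
            if taken == k:
                break
            if rec.id in chosen:
                continue
            walked += 1
            label = oracle(rec.image)
            if label is UNIDENTIFIABLE:
                continue
            chosen[rec.id] = replace(
                rec.image, label=int(label), true_label=int(label), noisy=False
            )
            report.append(
                _row(rec, name, replaced=walked > k, oracle_label=int(label))
            )
            taken += 1
        if taken < k and not whole_pool:
            raise ValueError(
                f"{name} tail exhausted: needed {k} identifiable images, found {taken} "
                f"(shortfall {k - taken})"
            )

    walk(records, config.k_over, "over")
    walk(list(reversed(records)), config.k_under, "under")
    ordered = [chosen[r.id] for r in records if r.id in chosen]
    return CountDataset(ordered), report


def _row(rec: DiscrepancyRecord, tail: str, replaced: bool, oracle_label) -> dict:
    return {
        "id": rec.id,
        "noisy_label": rec.noisy_label,
        "predicted": rec.predicted_count,
        "residual": rec.residual,
        "tail": tail,
        "replaced_flag": replaced,
        "oracle_label": oracle_label,
    }


def refine(
    model: CountRegressor,
    subset1: CountDataset,
    subset2: CountDataset,
    config: RefinementConfig,
) -> tuple[CountRegressor, list[dict]]:
    """Fine-tune the whole model on subset1 + relabelled subset2.

    The merged set is re-split 80/20 (uniform random, seeded from the train
    config); all sections are unfrozen; the best-validation-epoch checkpoint
    is returned together with the phase history.
    """
    overlap = set(subset1.ids) & set(subset2.ids)
    if overlap:
        raise ValueError(f"subsets share image ids: {sorted(overlap)[:5]}")
    merged = CountDataset(list(subset1.items) + list(subset2.items))
    if config.finetune_phase.epochs == 0:
        return model, []
    train, val = train_val_split(
        merged, config.train_fraction, seed=config.train_config.seed
    )
    if config.finetune_phase.frozen_sections:
        raise ValueError("refinement fine-tuning must train all sections")
    return train_phase(model, train, val, config.finetune_phase, config.train_config)
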