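"""End-to-end experiment orchestration: generate → split → train → evaluate → refine → CAM.

Two experiment shapes are provided.  A *counting experiment* mirrors the
clean-label workflow: generate a skewed synthetic dataset, build a binned
stratified test set, train with the two-phase protocol and report R²/RMSE/MAE
plus totals.  A *refinement experiment* mirrors the noisy-archive workflow:
the model first trains on a clean subset biased towards low counts, then a
noisy high-count pool is ranked by prediction discrepancy, the extreme tails
are oracle-relabelled and the model is fine-tuned on the extended set —
reported as paired Step 1 / Step 2 metric reports on one shared test set.

All stage seeds derive from one global seed by fixed offsets, so a config is
a single reproducibility knob.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import yaml

from .cam import compute_cam, overlay
from .data import CountDataset, SplitSpec, assign_bins, stratified_test_split, train_val_split
from .io import save_checkpoint, write_history, write_id_list
from .metrics import MetricReport, compute_metrics, export_scatter
from .model import BackboneSpec, RegressionHeadSpec, build_regressor
from .refine import RefinementConfig, rank_discrepancies, refine, select_refinement_set
from .synthetic import DotSceneSpec, LabelNoiseModel, RingImageSpec, make_dataset
from .train import PhaseSpec, TrainConfig, desk_protocol, run_protocol

__all__ = [
    "ExperimentConfig",
    "run_counting_experiment",
    "run_refinement_experiment",
    "desk_counting_config",
    "desk_refinement_config",
    "stage_seed",
]

_OFFSETS = {"data": 1000, "split": 2000, "train": 3000, "noise": 4000, "refine": 5000}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + _OFFSETS[stage]) % (2**31 - 1)


@dataclass
class ExperimentConfig:
    scenario: str = "dot"  # "dot" or "ring"
    generator: DotSceneSpec | RingImageSpec | None = None
    n_images: int = 870
    count_distribution: dict[int, float] | None = None
    split: SplitSpec = field(default_factory=lambda: SplitSpec(n_bins=8, per_bin=15))
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    head: RegressionHeadSpec = field(default_factory=RegressionHeadSpec)
    head_phase: PhaseSpec | None = None
    finetune_phase: PhaseSpec | None = None
    train_config: TrainConfig | None = None
    refinement: RefinementConfig | None = None
    noise: LabelNoiseModel = field(default_factory=LabelNoiseModel)
    clean_cap_fraction: float = 0.4  # clean subset keeps the lower 40% of the count range
    clean_subset_size: int | None = None
    train_size: int | None = None  # optionally truncate the train split
    val_size: int | None = None
    seed: int = 0
    out_dir: str | Path | None = None
    n_cam_examples: int = 4

    def __post_init__(self):
        if self.scenario not in {"dot", "ring"}:
            raise ValueError("scenario must be 'dot' or 'ring'")
        if self.generator is None:
            self.generator = DotSceneSpec() if self.scenario == "dot" else RingImageSpec()
        if self.head_phase is None or self.finetune_phase is None or self.train_config is None:
            head, finetune, tc = desk_protocol(seed=stage_seed(self.seed, "train"))
            self.head_phase = self.head_phase or head
            self.finetune_phase = self.finetune_phase or finetune
            self.train_config = self.train_config or tc


def _normalization_from(train: CountDataset) -> tuple[float, float]:
    sample = np.stack([im.pixels for im in train.items[:128]])
    return float(sample.mean()), float(max(sample.std(), 1e-3))


def _build_and_train(config: ExperimentConfig, train, val):
    tc = dc_replace(config.train_config, seed=stage_seed(config.seed, "train"))
    model = build_regressor(
        config.backbone,
        config.head,
        seed=stage_seed(config.seed, "train"),
        normalization=_normalization_from(train),
    )
    model, history = run_protocol(
        model, train, val, config.head_phase, config.finetune_phase, tc
    )
    return model, history, tc

def _evaluate(model, test: CountDataset) -> tuple[MetricReport, np.ndarray]:
    preds = model.predict(test.items)
    return compute_metrics(test.labels, preds), preds


def _write_common(out: Path, config: ExperimentConfig, splits: dict, histories: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": config.scenario,
        "n_images": config.n_images,
        "seed": config.seed,
        "backbone": config.backbone.name,
        "split": {"n_bins": config.split.n_bins, "per_bin": config.split.per_bin},
        "optimizer": {"kind": "adam", "beta1": 0.9, "beta2": 0.99, "eps": 1e-5, "weight_decay": 1e-2},
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh)
    for name, ds in splits.items():
        write_id_list(ds.ids, out / f"{name}_ids.txt")
    for name, hist in histories.items():
        write_history(hist, out / f"history_{name}.csv")


def _write_cams(out: Path, model, test: CountDataset, n: int) -> list[Path]:
    paths = []
    for im in test.items[:n]:
        hm = compute_cam(model, im)
        paths.append(overlay(im, hm, out / "cams" / f"{im.id}.png"))
    return paths


def _report_yaml(report: MetricReport, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(report.as_dict(), fh)


def run_counting_experiment(config: ExperimentConfig):
    """Clean-label experiment; returns ``(report, artifacts)``.

    ``artifacts`` holds the trained model, the splits, per-phase histories,
    test predictions and (when ``out_dir`` is set) the written file paths.
    """
    dataset = make_dataset(
        config.generator, config.n_images, config.count_distribution,
        seed=stage_seed(config.seed, "data"),
    )
    binned = assign_bins(dataset, config.split.n_bins)
    split = dc_replace(config.split, seed=stage_seed(config.seed, "split"))
    test, remainder = stratified_test_split(binned, split)
    train, val = train_val_split(
        remainder, config.split.train_fraction, seed=stage_seed(config.seed, "split") + 1
    )
    if config.train_size is not None:
        train = train.subset(range(min(config.train_size, len(train))))
    if config.val_size is not None:
        val = val.subset(range(min(config.val_size, len(val))))
    model, history, tc = _build_and_train(config, train, val)
    report, preds = _evaluate(model, test)

    artifacts = {
        "model": model,
        "train": train,
        "val": val,
        "test": test,
        "history": history,
        "predictions": preds,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_common(out, config, {"train": train, "val": val, "test": test}, history)
        export_scatter(test.labels, preds, out / "scatter.csv")
        _report_yaml(report, out / "metrics.yaml")
        save_checkpoint(model, out / "checkpoint.npz", extra={"seed": config.seed})
        artifacts["cam_paths"] = _write_cams(out, model, test, config.n_cam_examples)
        artifacts["out_dir"] = out
    return report, artifacts


def run_refinement_experiment(config: ExperimentConfig):
    """Noisy-label experiment; returns ``(step1_report, step2_report, artifacts)``.

    The clean subset is truncated to the lower part of the count range (a
    quality-biased training archive); the remaining pool keeps high counts
    but carries undercount label noise.  Step 2 fine-tunes on the clean
    subset plus the oracle-relabelled discrepancy selection.
    """
    if config.refinement is None:
        raise ValueError("refinement experiment requires config.refinement")
    dataset = make_dataset(
        config.generator, config.n_images, config.count_distribution,
        seed=stage_seed(config.seed, "data"),
    )
    binned = assign_bins(dataset, config.split.n_bins)
    split = dc_replace(config.split, seed=stage_seed(config.seed, "split"))
    test, remainder = stratified_test_split(binned, split)

    lo, hi = (
        config.generator.count_range
        if isinstance(config.generator, DotSceneSpec)
        else config.generator.ring_count_range
    )
    cap = lo + config.clean_cap_fraction * (hi - lo)
    clean_idx = [i for i, im in enumerate(remainder.items) if im.label <= cap]
    if config.clean_subset_size is not None:
        clean_idx = clean_idx[: config.clean_subset_size]
    clean = remainder.subset(clean_idx)
    pool = remainder.subset(
        [i for i in range(len(remainder)) if i not in set(clean_idx)]
    )
    from .synthetic import corrupt_labels

    pool = corrupt_labels(pool, config.noise, seed=stage_seed(config.seed, "noise"))

    train1, val1 = train_val_split(
        clean, config.split.train_fraction, seed=stage_seed(config.seed, "split") + 1
    )
    model, history1, tc = _build_and_train(config, train1, val1)
    report1, preds1 = _evaluate(model, test)
    step1_state = copy.deepcopy(model.state_dict())

    records = rank_discrepancies(model, pool)
    refinement = config.refinement
    refinement.train_config = dc_replace(
        refinement.train_config, seed=stage_seed(config.seed, "refine"),
        augmentation=tc.augmentation, batch_size=tc.batch_size,
    )
    subset2, selection_report = select_refinement_set(records, refinement)
    model, history2 = refine(model, clean, subset2, refinement)
    report2, preds2 = _evaluate(model, test)

    artifacts = {
        "model": model,
        "step1_state": step1_state,
        "test": test,
        "clean": clean,
        "pool": pool,
        "subset2": subset2,
        "selection_report": selection_report,
        "histories": {"step1": history1, "step2": history2},
        "predictions_step1": preds1,
        "predictions_step2": preds2,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _write_common(
            out, config,
            {"clean": clean, "pool": pool, "test": test, "subset2": subset2},
            {**history1, "refine": history2},
        )
        import csv as _csv

        with open(out / "selection.csv", "w", newline="", encoding="utf-8") as fh:
            rows = [r for r in selection_report]
            writer = _csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else ["id"])
            writer.writeheader()
            writer.writerows(rows)
        _report_yaml(report1, out / "metrics_step1.yaml")
        _report_yaml(report2, out / "metrics_step2.yaml")
        export_scatter(test.labels, preds1, out / "scatter_step1.csv")
        export_scatter(test.labels, preds2, out / "scatter_step2.csv")
        save_checkpoint(model, out / "checkpoint_step2.npz", extra={"seed": config.seed})
        artifacts["out_dir"] = out
    return report1, report2, artifacts


def desk_counting_config(seed: int = 0, out_dir=None) -> ExperimentConfig:
    """Reference desk-scale counting experiment.

    Dot scenes at 64x64 with counts 0-30 under a geometric-decay label
    distribution (factor 0.93, so high-count images are scarce but every
    test bin stays fillable), a 1200-image pool, an 8-bin x 15-per-bin
    stratified test set (n=120) and 600/150 train/validation images; the
    tiny backbone trains with the two-phase desk protocol.
    """
    from .synthetic import geometric_weights
    from .train import desk_protocol

    head, finetune, tc = desk_protocol(seed=stage_seed(seed, "train"))
    return ExperimentConfig(
        scenario="dot",
        generator=DotSceneSpec(),
        n_images=1200,
        count_distribution=geometric_weights(0, 30, 0.93),
        split=SplitSpec(n_bins=8, per_bin=15),
        head_phase=head,
        finetune_phase=finetune,
        train_config=tc,
        train_size=600,
        val_size=150,
        seed=seed,
        out_dir=out_dir,
    )


def desk_refinement_config(seed: int = 0, out_dir=None) -> ExperimentConfig:
    """Reference desk-scale two-step refinement experiment.

    Counts span 0-49; the clean training subset keeps only the lower 40% of
    the count range (quality-biased archive), while the remaining pool keeps
    the high counts but carries undercount label noise (70% corruption,
    retained fraction 0.4-0.95).  The 25 most over- and 25 most
    under-estimated pool images are oracle-relabelled and the model is
    fine-tuned on the extended set.
    """
    from .synthetic import geometric_weights
    from .train import PhaseSpec, desk_protocol
    from .train import _discriminative

    head, finetune, tc = desk_protocol(seed=stage_seed(seed, "train"))
    refinement = RefinementConfig(
        k_over=25,
        k_under=25,
        finetune_phase=PhaseSpec(epochs=12, section_lrs=_discriminative(3e-4, 3e-3)),
        train_config=tc,
    )
    return ExperimentConfig(
        scenario="dot",
        generator=DotSceneSpec(count_range=(0, 49)),
        n_images=1200,
        count_distribution=geometric_weights(0, 49, 0.95),
        split=SplitSpec(n_bins=10, per_bin=6),
        head_phase=head,
        finetune_phase=finetune,
        train_config=tc,
        refinement=refinement,
        noise=LabelNoiseModel(),
        clean_cap_fraction=0.4,
        clean_subset_size=320,
        seed=seed,
        out_dir=out_dir,
    )


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a plain-YAML-friendly mapping.

    Recognised keys: ``scenario``, ``n_images``, ``seed``, ``out_dir``,
    ``n_bins``, ``per_bin``, ``head_epochs``, ``finetune_epochs``,
    ``batch_size``, ``train_size``, ``val_size``, ``clean_subset_size``,
    ``clean_cap_fraction``, ``count_range``, ``decay`` and an optional
    ``refinement`` mapping with ``k_over``/``k_under``/``epochs``.
    """
    from .synthetic import geometric_weights
    from .train import PhaseSpec, _discriminative, desk_protocol

    raw = dict(raw)
    scenario = raw.get("scenario", "dot")
    seed = int(raw.get("seed", 0))
    count_range = tuple(raw.get("count_range", (0, 30) if scenario == "dot" else (1, 63)))
    generator = (
        DotSceneSpec(count_range=count_range)
        if scenario == "dot"
        else RingImageSpec(ring_count_range=count_range)
    )
    head, finetune, tc = desk_protocol(
        head_epochs=int(raw.get("head_epochs", 10)),
        finetune_epochs=int(raw.get("finetune_epochs", 12)),
        batch_size=int(raw.get("batch_size", 50)),
        seed=stage_seed(seed, "train"),
    )
    refinement = None
    if raw.get("refinement"):
        r = raw["refinement"]
        refinement = RefinementConfig(
            k_over=int(r.get("k_over", 50)),
            k_under=int(r.get("k_under", 50)),
            finetune_phase=PhaseSpec(
                epochs=int(r.get("epochs", 12)),
                section_lrs=_discriminative(3e-4, 3e-3),
            ),
            train_config=tc,
        )
    return ExperimentConfig(
        scenario=scenario,
        generator=generator,
        n_images=int(raw.get("n_images", 1200)),
        count_distribution=geometric_weights(*count_range, float(raw.get("decay", 0.93))),
        split=SplitSpec(
            n_bins=int(raw.get("n_bins", 8)), per_bin=int(raw.get("per_bin", 15))
        ),
        head_phase=head,
        finetune_phase=finetune,
        train_config=tc,
        refinement=refinement,
        clean_cap_fraction=float(raw.get("clean_cap_fraction", 0.4)),
        clean_subset_size=raw.get("clean_subset_size"),
        train_size=raw.get("train_size"),
        val_size=raw.get("val_size"),
        seed=seed,
        out_dir=raw.get("out_dir"),
    )
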