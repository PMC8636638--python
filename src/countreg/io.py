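"""Disk formats: PNG images with a CSV label manifest, checkpoints, histories.

A dataset directory looks like::

    <dir>/images/<id>.png          8-bit greyscale (or RGB)
    <dir>/labels.csv               image_path,count,true_count,unidentifiable,noisy
    <dir>/manifest.yaml            summary metadata

Checkpoints pair an ``.npz`` weight archive with a YAML manifest recording
the backbone/head specification, normalization and provenance.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml
from PIL import Image as PILImage

from .data import CountDataset, LabelledImage
from .model import BackboneSpec, CountRegressor, RegressionHeadSpec, build_regressor

__all__ = [
    "write_dataset",
    "read_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "write_id_list",
    "write_history",
]

_CSV_FIELDS = ["image_path", "count", "true_count", "unidentifiable", "noisy"]


def write_dataset(dataset: CountDataset, directory) -> Path:
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in dataset:
        rel = f"images/{im.id}.png"
        arr = (np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)
        PILImage.fromarray(arr).save(directory / rel)
        rows.append(
            {
                "image_path": rel,
                "count": im.label,
                "true_count": "" if im.true_label is None else im.true_label,
                "unidentifiable": int(im.unidentifiable),
                "noisy": int(im.noisy),
            }
        )
    with open(directory / "labels.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerows(rows)
    with open(directory / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataset.label_summary(), fh)
    return directory


def read_dataset(directory) -> CountDataset:
    directory = Path(directory)
    manifest = directory / "labels.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no labels.csv under {directory}")
    items = []
    with open(manifest, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(PILImage.open(directory / row["image_path"]), dtype=np.float32)
            img /= 255.0
            items.append(
                LabelledImage(
                    pixels=img,
                    label=int(row["count"]),
                    true_label=int(row["true_count"]) if row["true_count"] != "" else None,
                    unidentifiable=bool(int(row["unidentifiable"])),
                    noisy=bool(int(row["noisy"])),
                    id=Path(row["image_path"]).stem,
                )
            )
    return CountDataset(items)


def save_checkpoint(model: CountRegressor, path, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    manifest = {
        "backbone": model.backbone_spec.name,
        "hidden_width": model.head_spec.hidden_width,
        "normalization": list(model.normalization),
        **(extra or {}),
    }
    with open(path.with_suffix(".yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh)
    return path


def load_checkpoint(path) -> CountRegressor:
    path = Path(path)
    with open(path.with_suffix(".yaml"), encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    model = build_regressor(
        BackboneSpec(name=manifest["backbone"]),
        RegressionHeadSpec(hidden_width=manifest["hidden_width"]),
        normalization=tuple(manifest["normalization"]),
    )
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model


def write_id_list(ids, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{i}\n" for i in ids), encoding="utf-8")
    return path


def write_history(history: list[dict], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if history:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
        else:
            fh.write("epoch,train_loss,val_loss,lr_head\n")
    return path
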