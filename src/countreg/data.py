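"""Dataset containers, binned stratified splitting and label-preserving augmentation.

Counting datasets are typically right-skewed: images with many objects are
scarce.  A test set drawn uniformly would barely exercise the high-count
regime, so the test set is built by binning images on their label and
sampling a fixed number per bin.  All augmentations here preserve the count
label: resizing squeezes (never crops), zooming is capped and compensated
with zero padding, so no counted object can leave the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import ProjectiveTransform, resize as _sk_resize, warp as _sk_warp

__all__ = [
    "LabelledImage",
    "CountDataset",
    "SplitSpec",
    "AugmentationPolicy",
    "assign_bins",
    "stratified_test_split",
    "train_val_split",
    "augment",
    "squeeze_resize",
]


@dataclass
class LabelledImage:
    """A raster image with a single image-level integer count label.

    ``label`` is the working annotation (possibly noisy); ``true_label``
    preserves the ground truth when known (synthetic data, or after oracle
    relabelling).  ``meta`` carries generator provenance such as object masks.
    """

    pixels: np.ndarray
    label: int
    id: str
    true_label: int | None = None
    noisy: bool = False
    unidentifiable: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label < 0:
            raise ValueError(f"label must be >= 0, got {self.label} for {self.id!r}")


class CountDataset:
    """Ordered collection of :class:`LabelledImage` with optional bin indices."""

    def __init__(self, items: list[LabelledImage], label_bins: np.ndarray | None = None):
        ids = [im.id for im in items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image ids in dataset: {dup[:5]}")
        self.items = list(items)
        self.label_bins = None if label_bins is None else np.asarray(label_bins, dtype=int)
        if self.label_bins is not None and len(self.label_bins) != len(self.items):
            raise ValueError("label_bins length must match number of items")

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            bins = None if self.label_bins is None else self.label_bins[idx]
            return CountDataset(self.items[idx], bins)
        return self.items[idx]

    def __iter__(self):
        return iter(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.items], dtype=int)

    @property
    def true_labels(self) -> np.ndarray:
        return np.array(
            [im.true_label if im.true_label is not None else im.label for im in self.items],
            dtype=int,
        )

    @property
    def ids(self) -> list[str]:
        return [im.id for im in self.items]

    def subset(self, indices) -> "CountDataset":
        indices = list(indices)
        bins = None if self.label_bins is None else self.label_bins[indices]
        return CountDataset([self.items[i] for i in indices], bins)

    def filter(self, predicate) -> "CountDataset":
        return self.subset([i for i, im in enumerate(self.items) if predicate(im)])

    def label_summary(self) -> dict:
        lab = self.labels
        return {
            "n": len(lab),
            "min": int(lab.min()),
            "max": int(lab.max()),
            "mean": float(lab.mean()),
            "sum": int(lab.sum()),
        }


@dataclass(frozen=True)
class SplitSpec:
    n_bins: int
    per_bin: int
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.per_bin < 0:
            raise ValueError("per_bin must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def assign_bins(dataset: CountDataset, n_bins: int) -> CountDataset:
    """Assign each image to one of ``n_bins`` equal-width label bins.

    Bins span the observed integer label range with width
    ``(max - min + 1) / n_bins``; the maximum label falls in the last bin.
    """
    if len(dataset) == 0:
        raise ValueError("cannot bin an empty dataset")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    labels = dataset.labels
    lo, hi = int(labels.min()), int(labels.max())
    if lo == hi and n_bins > 1:
        raise ValueError(
            f"all labels equal {lo}; cannot form {n_bins} bins over a degenerate range"
        )
    width = (hi - lo + 1) / n_bins
    bins = np.minimum(((labels - lo) / width).astype(int), n_bins - 1)
    return CountDataset(dataset.items, bins)


def stratified_test_split(
    dataset: CountDataset, spec: SplitSpec
) -> tuple[CountDataset, CountDataset]:
    """Draw ``per_bin`` images uniformly without replacement from each label bin.

    Returns ``(test, remainder)``; together they partition the input.  The
    input is binned with ``spec.n_bins`` if bins are not already assigned.
    """
    if dataset.label_bins is None or (
        dataset.label_bins.max(initial=-1) >= spec.n_bins
    ):
        dataset = assign_bins(dataset, spec.n_bins)
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    for b in range(spec.n_bins):
        members = np.flatnonzero(dataset.label_bins == b)
        if len(members) < spec.per_bin:
            raise ValueError(
                f"bin {b} holds {len(members)} images but {spec.per_bin} are "
                f"required for the test set"
            )
        if spec.per_bin:
            test_idx.extend(rng.choice(members, size=spec.per_bin, replace=False))
    chosen = set(test_idx)
    test = dataset.subset(sorted(chosen))
    remainder = dataset.subset([i for i in range(len(dataset)) if i not in chosen])
    return test, remainder


def train_val_split(
    dataset: CountDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[CountDataset, CountDataset]:
    """Random split into train/validation; train size is floor(fraction * n)."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train_idx = set(perm[:n_train].tolist())
    train = dataset.subset([i for i in range(n) if i in train_idx])
    val = dataset.subset([i for i in range(n) if i not in train_idx])
    return train, val


@dataclass(frozen=True)
class AugmentationPolicy:
    """Label-preserving augmentation: squeeze-resize, flip, lighting, warp, zoom.

    The resize is aspect-ratio-nonpreserving (a squeeze, never a crop).
    ``max_zoom_fraction`` stays small because zooming in can push counted
    objects out of frame; zoom-out is compensated with zero padding.  With
    the generators' placement margin, the 10% default cannot cut out an
    object.
    """

    target_height: int = 64
    target_width: int = 64
    horizontal_flip_probability: float = 0.5
    lighting_jitter_range: tuple[float, float] = (0.9, 1.1)
    warp_magnitude: float = 0.0
    max_zoom_fraction: float = 0.1
    padding_mode: str = "zeros"

    def __post_init__(self):
        if not 0.0 <= self.max_zoom_fraction < 0.5:
            raise ValueError("max_zoom_fraction must be in [0, 0.5)")
        if self.padding_mode != "zeros":
            raise ValueError("only zero-padding is supported")


def squeeze_resize(pixels: np.ndarray, height: int, width: int) -> np.ndarray:
    """Resize to exactly (height, width), squeezing rather than cropping."""
    if pixels.shape[:2] == (height, width):
        return pixels
    return _sk_resize(
        pixels, (height, width), order=1, anti_aliasing=pixels.shape[0] > height
    ).astype(pixels.dtype)


def _zoom(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Zoom about the centre; zoom-out is zero-padded, zoom-in centre-trimmed."""
    h, w = pixels.shape[:2]
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    scaled = _sk_resize(pixels, (nh, nw), order=1, anti_aliasing=factor < 1)
    out = np.zeros_like(pixels, shape=(h, w) + pixels.shape[2:])
    if factor >= 1:
        top, left = (nh - h) // 2, (nw - w) // 2
        out[...] = scaled[top : top + h, left : left + w]
    else:
        top, left = (h - nh) // 2, (w - nw) // 2
        out[top : top + nh, left : left + nw] = scaled
    return out.astype(pixels.dtype)


def augment(
    image: LabelledImage, policy: AugmentationPolicy, rng: np.random.Generator
) -> LabelledImage:
    """Apply one random draw of the policy; the count label never changes."""
    px = np.asarray(image.pixels, dtype=np.float32)
    if px.size == 0:
        raise ValueError("cannot augment an empty image")
    px = squeeze_resize(px, policy.target_height, policy.target_width)

    if rng.random() < policy.horizontal_flip_probability:
        px = px[:, ::-1].copy()

    if policy.max_zoom_fraction > 0:
        factor = 1.0 + rng.uniform(-policy.max_zoom_fraction, policy.max_zoom_fraction)
        if abs(factor - 1.0) > 1e-3:
            px = _zoom(px, factor)

    if policy.warp_magnitude > 0:
        h, w = px.shape[:2]
        src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
        jitter = rng.uniform(-policy.warp_magnitude, policy.warp_magnitude, size=(4, 2))
        dst = src + jitter * [w, h]
        if hasattr(ProjectiveTransform, "from_estimate"):
            tform = ProjectiveTransform.from_estimate(dst, src)
        else:  # older scikit-image
            tform = ProjectiveTransform()
            tform.estimate(dst, src)
        px = _sk_warp(px, tform.inverse, output_shape=px.shape, cval=0.0).astype(np.float32)

    lo, hi = policy.lighting_jitter_range
    if (lo, hi) != (1.0, 1.0):
        px = np.clip(px * rng.uniform(lo, hi), 0.0, 1.0)

    return replace(image, pixels=px.astype(np.float32))
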