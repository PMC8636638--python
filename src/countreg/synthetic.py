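"""Seeded synthetic counting benchmarks: dot scenes and concentric-ring images.

Two families of images, each with an exact ground-truth count label:

* **Dot scenes** emulate aerial wildlife survey photographs (e.g. hauled-out
  seals): bright anti-aliased ellipses of variable scale, elongation and
  orientation on a textured background, under scene-level lighting
  variation, optionally with smaller cross-shaped distractor marks
  (bird-like objects that are never counted).
* **Ring images** emulate otolith micrographs: concentric post-settlement
  growth rings rendered strictly outside a central accessory-growth-centre
  (AGC) disc, whose pre-settlement structure is excluded from the count.

A label-noise model reproduces the archival annotation defect of overlapping
aerial images: individuals appearing in several frames are counted once, so
noisy labels only ever *under*-count.  Everything is a pure function of
(spec, seed) and therefore bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import CountDataset, LabelledImage

__all__ = [
    "DotSceneSpec",
    "RingImageSpec",
    "LabelNoiseModel",
    "UNIDENTIFIABLE",
    "generate_dot_scene",
    "generate_ring_image",
    "make_dataset",
    "corrupt_labels",
    "oracle_relabel",
    "sample_counts",
    "geometric_weights",
]


class _Unidentifiable:
    """Sentinel returned by the oracle for images it cannot count."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNIDENTIFIABLE"


UNIDENTIFIABLE = _Unidentifiable()


@dataclass(frozen=True)
class DotSceneSpec:
    """Parameters of a dot-field scene.

    ``object_scale_range`` is the scene-level object diameter as a fraction
    of image width (drawn once per scene, emulating camera distance); each
    object jitters around it.  ``lighting_jitter`` is a scene-level
    multiplicative intensity factor.  Distractors are smaller, dimmer,
    cross-shaped marks that must never enter the count label.
    """

    image_height: int = 64
    image_width: int = 64
    count_range: tuple[int, int] = (0, 30)
    object_scale_range: tuple[float, float] = (0.05, 0.11)
    elongation_range: tuple[float, float] = (1.0, 1.8)
    background_texture_amplitude: float = 0.05
    lighting_jitter: tuple[float, float] = (0.8, 1.2)
    overlap_allowed: bool = False
    distractor_count_range: tuple[int, int] = (0, 3)
    placement_margin: float = 0.14  # fraction of width kept clear at each border

    def __post_init__(self):
        if self.count_range[0] < 0:
            raise ValueError("count_range lower bound must be >= 0")
        if not (0.0 < self.object_scale_range[0] <= self.object_scale_range[1] < 0.5):
            raise ValueError("object_scale_range must lie within (0, 0.5)")


@dataclass(frozen=True)
class RingImageSpec:
    """Parameters of a concentric-ring image.

    Rings are Gaussian ridges at radii ``agc_radius + spacing*(i+1)``,
    strictly outside the AGC disc; ``zoom_levels`` emulate the discrete
    microscope magnifications of archival imagery.
    """

    image_height: int = 256
    image_width: int = 256
    ring_count_range: tuple[int, int] = (1, 63)
    ring_spacing: float = 1.7
    ring_contrast: float = 0.35
    agc_radius: float = 12.0
    blur_sigma: float = 0.6
    zoom_levels: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if self.ring_count_range[0] < 1:
            raise ValueError("ring_count_range lower bound must be >= 1")
        half = min(self.image_height, self.image_width) / 2
        zmax = max(self.zoom_levels)
        reach = zmax * (self.agc_radius + self.ring_spacing * (self.ring_count_range[1] + 1))
        if reach > half:
            raise ValueError(
                f"ring pattern (radius {reach:.1f}px at max count/zoom) exceeds the "
                f"image half-width ({half:.1f}px); reduce ring_spacing or ring_count_range"
            )


@dataclass(frozen=True)
class LabelNoiseModel:
    """Undercount-only label noise emulating overlapping-image deduplication.

    With probability ``corruption_probability`` an image's label becomes
    ``floor(true_count * f)`` with ``f`` drawn from
    ``retained_fraction_range``.  Images whose scene-level object scale is
    below ``unidentifiable_scale_threshold`` are flagged unidentifiable (too
    small to recount by eye).
    """

    corruption_probability: float = 0.7
    retained_fraction_range: tuple[float, float] = (0.4, 0.95)
    unidentifiable_scale_threshold: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.corruption_probability <= 1.0:
            raise ValueError("corruption_probability must be in [0, 1]")
        lo, hi = self.retained_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("retained_fraction_range must lie within (0, 1]")


def _render_ellipse(img, mask, yy, xx, cy, cx, a, b, theta, intensity):
    """Additively blend one anti-aliased ellipse; update the coverage mask."""
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    # ~1px soft edge expressed in normalised radius units
    soft = 1.0 / min(a, b)
    cover = np.clip((1.0 - rho) / soft + 0.5, 0.0, 1.0)
    np.maximum(img, cover * intensity, out=img)
    mask |= rho < 1.0


def generate_dot_scene(spec: DotSceneSpec, count: int, seed: int) -> LabelledImage:
    """Render a scene with exactly ``count`` countable objects.

    The returned image carries the exact label, the scene-level object scale
    and boolean foreground/distractor masks in ``meta``.  Identical
    ``(spec, count, seed)`` yields bit-identical images.
    """
    lo, hi = spec.count_range
    if not lo <= count <= hi:
        raise ValueError(f"count {count} outside spec.count_range {spec.count_range}")
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)

    base = rng.uniform(0.05, 0.2)
    img = np.full((h, w), base, dtype=np.float32)
    if spec.background_texture_amplitude > 0:
        noise = rng.normal(0.0, 1.0, size=(h, w))
        noise = gaussian_filter(noise, sigma=2.0)
        noise /= max(np.abs(noise).max(), 1e-9)
        img += (spec.background_texture_amplitude * noise).astype(np.float32)

    scene_scale = rng.uniform(*spec.object_scale_range)
    margin = spec.placement_margin * w
    if not spec.overlap_allowed and count > 0:
        # crowded scenes are rendered as if photographed from farther away:
        # cap the object diameter so random sequential placement stays feasible
        # (~28% disc coverage of the usable area)
        usable = min(h, w) - 2 * margin
        feasible_d = 2 * (usable * np.sqrt(0.28 / (np.pi * count)) - 0.9)
        scene_scale = min(scene_scale, max(feasible_d, 2.4) / w)
    obj_mask = np.zeros((h, w), dtype=bool)
    dis_mask = np.zeros((h, w), dtype=bool)

    placed: list[tuple[float, float, float]] = []  # (cy, cx, radius)

    def _place(radius: float) -> tuple[float, float]:
        for _ in range(300):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if spec.overlap_allowed:
                return cy, cx
            ok = all(
                np.hypot(cy - py, cx - px) > radius + pr + 1.8 for py, px, pr in placed
            )
            if ok:
                return cy, cx
        raise RuntimeError(
            f"could not place object of radius {radius:.1f}px without overlap; "
            f"scene too crowded for count={count} at {w}x{h}"
        )

    fg = np.zeros((h, w), dtype=np.float32)
    for _ in range(count):
        d = scene_scale * w * rng.uniform(0.85, 1.2)
        a = max(d / 2.0, 1.0)
        elong = rng.uniform(*spec.elongation_range)
        b = max(a / elong, 0.8)
        theta = rng.uniform(0, np.pi)
        cy, cx = _place(a)
        placed.append((cy, cx, a))
        _render_ellipse(fg, obj_mask, yy, xx, cy, cx, a, b, theta, rng.uniform(0.75, 1.0))

    n_dis = int(rng.integers(spec.distractor_count_range[0], spec.distractor_count_range[1] + 1))
    for _ in range(n_dis):
        # distractors: smaller, dimmer, strongly elongated bar-like marks
        d = scene_scale * w * rng.uniform(0.35, 0.55)
        a = max(d / 2.0, 0.9)
        b = max(a / 3.5, 0.6)
        theta = rng.uniform(0, np.pi)
        cy, cx = _place(a)
        placed.append((cy, cx, a))
        _render_ellipse(fg, dis_mask, yy, xx, cy, cx, a, b, theta, rng.uniform(0.45, 0.65))

    img = np.maximum(img, fg)
    light = rng.uniform(*spec.lighting_jitter)
    img = np.clip(img * light, 0.0, 1.0).astype(np.float32)

    return LabelledImage(
        pixels=img,
        label=count,
        true_label=count,
        id=f"dot-{seed:010d}",
        meta={
            "kind": "dot",
            "object_scale": float(scene_scale),
            "object_mask": obj_mask,
            "distractor_mask": dis_mask,
            "lighting": float(light),
        },
    )


def generate_ring_image(spec: RingImageSpec, ring_count: int, seed: int) -> LabelledImage:
    """Render ``ring_count`` concentric rings outside the AGC disc."""
    lo, hi = spec.ring_count_range
    if not lo <= ring_count <= hi:
        raise ValueError(
            f"ring_count {ring_count} outside spec.ring_count_range {spec.ring_count_range}"
        )
    rng = np.random.default_rng(seed)
    h, w = spec.image_height, spec.image_width
    zoom = float(spec.zoom_levels[rng.integers(len(spec.zoom_levels))])
    half = min(h, w) / 2
    reach = zoom * (spec.agc_radius + spec.ring_spacing * (ring_count + 1))
    if reach > half:
        raise ValueError(
            f"ring pattern radius {reach:.1f}px exceeds image half-width {half:.1f}px"
        )

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)

    agc = spec.agc_radius * zoom
    spacing = spec.ring_spacing * zoom
    img = np.full((h, w), 0.15, dtype=np.float32)
    # smooth bright accessory growth centre: monotone profile, no ring maxima
    img += 0.35 * np.exp(-((r / max(agc, 1e-6)) ** 2)).astype(np.float32)

    sigma_r = 0.28 * spacing
    radii = agc + spacing * (np.arange(ring_count) + 1.0)
    amp = spec.ring_contrast * rng.uniform(0.85, 1.15, size=ring_count)
    for ri, ai in zip(radii, amp):
        img += (ai * np.exp(-((r - ri) ** 2) / (2 * sigma_r**2))).astype(np.float32)

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return LabelledImage(
        pixels=img,
        label=ring_count,
        true_label=ring_count,
        id=f"ring-{seed:010d}",
        meta={
            "kind": "ring",
            "zoom": zoom,
            "agc_radius": float(agc),
            "ring_radii": radii,
        },
    )


def geometric_weights(lo: int, hi: int, decay: float = 0.9) -> dict[int, float]:
    """Right-skewed categorical weights over counts: high counts are scarce."""
    return {c: decay ** (c - lo) for c in range(lo, hi + 1)}


def sample_counts(
    weights: dict[int, float], n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` labels from normalised categorical weights (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = np.array(sorted(weights), dtype=int)
    w = np.array([weights[c] for c in counts], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    return rng.choice(counts, size=n, p=w / w.sum())


def make_dataset(
    spec: DotSceneSpec | RingImageSpec,
    n_images: int,
    count_distribution: dict[int, float] | None = None,
    seed: int = 0,
) -> CountDataset:
    """Generate a dataset whose labels follow the given categorical weights.

    By default the weights decay geometrically with the count (factor 0.9),
    reproducing the right-skewed distributions of archival counting data
    where high-count images are scarce.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if isinstance(spec, DotSceneSpec):
        lo, hi = spec.count_range
        gen = generate_dot_scene
    else:
        lo, hi = spec.ring_count_range
        gen = generate_ring_image
    weights = count_distribution or geometric_weights(lo, hi)
    if any(c < lo or c > hi for c in weights):
        raise ValueError("count_distribution contains counts outside the spec range")
    labels = sample_counts(weights, n_images, seed)
    master = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    image_seeds = master.integers(0, 2**31 - 1, size=n_images)
    items = [gen(spec, int(c), int(s)) for c, s in zip(labels, image_seeds)]
    return CountDataset(items)


def corrupt_labels(
    dataset: CountDataset, noise: LabelNoiseModel, seed: int = 0
) -> CountDataset:
    """Apply undercount label noise; the true label survives in metadata."""
    rng = np.random.default_rng(seed)
    out = []
    for im in dataset:
        true = im.true_label if im.true_label is not None else im.label
        unident = (
            im.meta.get("object_scale", np.inf) < noise.unidentifiable_scale_threshold
        )
        if rng.random() < noise.corruption_probability:
            f = rng.uniform(*noise.retained_fraction_range)
            new_label = int(np.floor(true * f))
            out.append(
                replace(
                    im,
                    label=new_label,
                    true_label=true,
                    noisy=True,
                    unidentifiable=bool(unident or im.unidentifiable),
                )
            )
        else:
            out.append(
                replace(
                    im,
                    true_label=true,
                    unidentifiable=bool(unident or im.unidentifiable),
                )
            )
    return CountDataset(out, dataset.label_bins)


def oracle_relabel(image: LabelledImage):
    """Ground-truth recount oracle (stands in for a human re-annotator).

    Returns the true count, or :data:`UNIDENTIFIABLE` when the image is
    flagged as impossible to recount by eye.
    """
    if image.unidentifiable:
        return UNIDENTIFIABLE
    if image.true_label is not None:
        return int(image.true_label)
    if not image.noisy:
        return int(image.label)
    raise ValueError(
        f"image {image.id!r} is noisy but carries no true-label metadata; "
        "the oracle cannot recount it"
    )
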