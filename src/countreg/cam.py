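"""Gradient-weighted class-activation maps for the scalar count output.

The classic CAM construction needs a single linear layer over pooled
features; the two-layer regression head breaks that assumption, so the
gradient-weighted variant is used instead: channel weights are the
spatially averaged gradients of the scalar output with respect to the last
convolutional block's activations, the weighted activation sum is
rectified (keeping only positively contributing regions), bilinearly
upsampled to image size and min-max normalised to [0, 1].  A constant raw
map (e.g. zero gradients everywhere) yields an all-zero heatmap by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _resize

from .data import LabelledImage
from .model import CountRegressor

__all__ = ["HeatMap", "compute_cam", "overlay"]


@dataclass(frozen=True)
class HeatMap:
    values: np.ndarray  # 2-D, in [0, 1], same spatial shape as the source image
    image_id: str
    checkpoint_id: str = ""


def compute_cam(model: CountRegressor, image: LabelledImage | np.ndarray) -> HeatMap:
    """Heatmap of the regions that drive the predicted count upward."""
    if model.cam_layer_index is None:
        raise ValueError("model has no convolutional block to derive a CAM from")
    pixels = image.pixels if isinstance(image, LabelledImage) else np.asarray(image)
    image_id = image.id if isinstance(image, LabelledImage) else ""
    out_shape = pixels.shape[:2]

    batch = model.prepare_batch([pixels])
    feats = model.backbone.forward(batch, train=True)
    model.head.forward(feats, train=True)

    model.backbone.zero_grad()
    model.head.zero_grad()
    dfeat = model.head.backward(np.ones((1, 1), dtype=np.float32))
    # gradient at the activation feeding the CAM layer's successor
    dact = model.backbone.backward(dfeat, stop_at=model.cam_layer_index + 1)
    act = model.backbone.output_of(model.cam_layer_index)

    weights = dact[0].mean(axis=(1, 2))  # (C,)
    raw = np.maximum((weights[:, None, None] * act[0]).sum(axis=0), 0.0)
    if raw.max() <= raw.min():
        values = np.zeros(out_shape, dtype=np.float32)
    else:
        up = _resize(raw, out_shape, order=1, anti_aliasing=False)
        up -= up.min()
        values = (up / up.max()).astype(np.float32)
    return HeatMap(values=values, image_id=image_id)


_INFERNO_STOPS = np.array(
    [
        [0.001, 0.000, 0.014],
        [0.341, 0.062, 0.429],
        [0.735, 0.215, 0.330],
        [0.978, 0.557, 0.034],
        [0.988, 0.998, 0.645],
    ]
)


def _colorize(values: np.ndarray) -> np.ndarray:
    """Map [0,1] heat to an inferno-like RGB ramp."""
    t = np.clip(values, 0.0, 1.0) * (len(_INFERNO_STOPS) - 1)
    i = np.minimum(t.astype(int), len(_INFERNO_STOPS) - 2)
    frac = (t - i)[..., None]
    return _INFERNO_STOPS[i] * (1 - frac) + _INFERNO_STOPS[i + 1] * frac


def overlay(
    image: LabelledImage | np.ndarray,
    heatmap: HeatMap,
    path,
    mode: str = "side-by-side",
    alpha: float = 0.5,
) -> Path:
    """Write a PNG pairing the image with its heatmap.

    ``mode`` is ``"side-by-side"`` (image left, coloured heatmap right) or
    ``"blend"`` (alpha-blended single panel).
    """
    pixels = image.pixels if isinstance(image, LabelledImage) else np.asarray(image)
    gray = pixels.mean(axis=2) if pixels.ndim == 3 else pixels
    if gray.shape != heatmap.values.shape:
        raise ValueError(
            f"image shape {gray.shape} does not match heatmap shape {heatmap.values.shape}"
        )
    heat_rgb = _colorize(heatmap.values)
    img_rgb = np.repeat(np.clip(gray, 0, 1)[..., None], 3, axis=2)
    if mode == "side-by-side":
        panel = np.concatenate([img_rgb, heat_rgb], axis=1)
    elif mode == "blend":
        panel = (1 - alpha) * img_rgb + alpha * heat_rgb
    else:
        raise ValueError(f"unknown overlay mode {mode!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray((panel * 255).astype(np.uint8)).save(path)
    return path
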