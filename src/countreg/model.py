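"""Count regressor: small convolutional backbone + two-layer regression head.

The head maps pooled backbone features to a ``hidden_width``-neuron layer and
then to a single continuous output — the predicted object count.  The network
is partitioned into three sections (early trunk, late trunk, head) so that
training can freeze the trunk or apply discriminative per-section learning
rates.  The training criterion is the Huber loss with threshold 1: quadratic
``0.5 r^2`` for residuals below 1 in magnitude, linear ``|r| - 0.5`` beyond,
averaged over the batch — robust to outlier counts because its per-element
gradient is bounded by 1/n.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .nn import Conv2d, Dense, GlobalAvgPool, MaxPool2x2, ReLU, Sequential

__all__ = [
    "BackboneSpec",
    "RegressionHeadSpec",
    "HuberLossSpec",
    "CountRegressor",
    "build_regressor",
    "huber_loss",
    "huber_loss_grad",
    "predict_counts",
    "BACKBONES",
]

# name -> (per-block channel widths, input spatial size)
BACKBONES: dict[str, dict] = {
    # 4 conv blocks, feature width 64, for 64x64 greyscale input
    "tiny": {"channels": (8, 16, 32, 64), "input_hw": (64, 64)},
    # 4 wider blocks, feature width 128: more capacity, ~4x the compute
    "tiny-wide": {"channels": (16, 32, 64, 128), "input_hw": (64, 64)},
    # 3 conv blocks, feature width 64: fastest option for smoke tests
    "micro": {"channels": (16, 32, 64), "input_hw": (32, 32)},
}


@dataclass(frozen=True)
class RegressionHeadSpec:
    hidden_width: int = 512
    output_width: int = 1

    def __post_init__(self):
        if self.output_width != 1:
            raise ValueError("regression head must map to a single scalar output")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")

    def parameter_count(self, feature_width: int) -> int:
        return (
            feature_width * self.hidden_width
            + self.hidden_width
            + self.hidden_width * self.output_width
            + self.output_width
        )


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny"
    pretrained: bool = False
    in_channels: int = 1

    def __post_init__(self):
        if self.name not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.name!r}; supported: {sorted(BACKBONES)}"
            )
        if self.pretrained:
            raise ValueError(
                "no pretrained weights ship with this package; "
                "set pretrained=False or load a checkpoint explicitly"
            )

    @property
    def feature_width(self) -> int:
        return BACKBONES[self.name]["channels"][-1]

    @property
    def input_hw(self) -> tuple[int, int]:
        return BACKBONES[self.name]["input_hw"]


@dataclass(frozen=True)
class HuberLossSpec:
    threshold: float = 1.0
    reduction: str = "mean"


def huber_loss(predictions, targets, threshold: float = 1.0) -> float:
    """Mean Huber loss over a batch.

    Each element contributes ``0.5 * r**2`` when ``|r| < threshold`` and
    ``threshold * (|r| - 0.5 * threshold)`` otherwise (for the default
    threshold 1 this is ``|r| - 0.5``); the loss is the batch mean.
    """
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("huber_loss requires a nonempty batch")
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} targets")
    r = np.abs(p - t)
    z = np.where(r < threshold, 0.5 * r**2, threshold * (r - 0.5 * threshold))
    return float(z.mean())


def huber_loss_grad(predictions, targets, threshold: float = 1.0) -> np.ndarray:
    """Gradient of the mean Huber loss w.r.t. the predictions.

    Clipped residual divided by the batch size; magnitude is bounded by
    ``threshold / n`` per element.
    """
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.size == 0 or p.size != t.size:
        raise ValueError("batches must be nonempty and of equal length")
    return np.clip(p - t, -threshold, threshold) / p.size


class CountRegressor:
    """Backbone + regression head mapping one image to one scalar count."""

    def __init__(
        self,
        backbone: Sequential,
        head: Sequential,
        backbone_spec: BackboneSpec,
        head_spec: RegressionHeadSpec,
        normalization: tuple[float, float] = (0.5, 0.25),
        cam_layer_index: int | None = None,
        section_split: int | None = None,
    ):
        self.backbone = backbone
        self.head = head
        self.backbone_spec = backbone_spec
        self.head_spec = head_spec
        self.normalization = normalization
        self.cam_layer_index = cam_layer_index
        # index into backbone.layers where trunk section 2 begins
        self.section_split = section_split
        self.input_hw = backbone_spec.input_hw

    # -- sections ---------------------------------------------------------
    @property
    def sections(self) -> dict[int, list]:
        """Three LR sections: 1 = early trunk, 2 = late trunk, 3 = head."""
        split = self.section_split if self.section_split is not None else len(self.backbone.layers) // 2
        return {
            1: self.backbone.layers[:split],
            2: self.backbone.layers[split:],
            3: self.head.layers,
        }

    # -- forward / predict ------------------------------------------------
    def prepare_batch(self, images) -> np.ndarray:
        """Stack images into a normalized (B, 1, H, W) float32 batch.

        Accepts LabelledImage objects or raw 2-D arrays; anything not already
        at the model's input size is squeeze-resized (aspect ratio is *not*
        preserved — no cropping, so no object can be cut out).
        """
        h, w = self.input_hw
        mean, std = self.normalization
        out = np.empty((len(images), 1, h, w), dtype=np.float32)
        for i, im in enumerate(images):
            px = im.pixels if hasattr(im, "pixels") else np.asarray(im)
            if px.ndim == 3:
                px = px.mean(axis=2)
            if px.shape != (h, w):
                px = _resize(px, (h, w), order=1, anti_aliasing=px.shape[0] > h)
            out[i, 0] = (px - mean) / std
        return out

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        feats = self.backbone.forward(batch, train=train)
        return self.head.forward(feats, train=train).ravel()

    def predict(self, images, batch_size: int = 128) -> np.ndarray:
        """Raw (unrounded, unclamped) predicted counts, deterministic."""
        preds = []
        for i in range(0, len(images), batch_size):
            chunk = images[i : i + batch_size]
            preds.append(self.forward(self.prepare_batch(chunk), train=False))
        return np.concatenate(preds) if preds else np.empty(0)

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for prefix, seq in (("backbone", self.backbone), ("head", self.head)):
            for i, layer in enumerate(seq.layers):
                for name, p in layer.params.items():
                    state[f"{prefix}.{i}.{name}"] = p.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, seq in (("backbone", self.backbone), ("head", self.head)):
            for i, layer in enumerate(seq.layers):
                for name in layer.params:
                    src = state[f"{prefix}.{i}.{name}"]
                    if src.shape != layer.params[name].shape:
                        raise ValueError(f"shape mismatch for {prefix}.{i}.{name}")
                    layer.params[name][...] = src

    def copy_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


def build_regressor(
    backbone: BackboneSpec | str = "tiny",
    head: RegressionHeadSpec | None = None,
    seed: int = 0,
    normalization: tuple[float, float] = (0.5, 0.25),
) -> CountRegressor:
    """Construct a count regressor.

    The classification-style output of the backbone is replaced by two
    fully-connected layers: pooled features -> ``hidden_width`` neurons ->
    one continuous output.  The output layer is zero-initialised, so an
    untrained model predicts exactly 0 for every image.
    """
    if isinstance(backbone, str):
        backbone = BackboneSpec(name=backbone)
    head = head or RegressionHeadSpec()
    cfg = BACKBONES[backbone.name]
    ss = np.random.SeedSequence(seed)
    layer_rngs = [np.random.default_rng(s) for s in ss.spawn(len(cfg["channels"]) + 1)]

    layers: list = []
    c_prev = backbone.in_channels
    last_relu = None
    for bi, c in enumerate(cfg["channels"]):
        layers.append(Conv2d(c_prev, c, rng=layer_rngs[bi]))
        layers.append(ReLU())
        last_relu = len(layers) - 1
        layers.append(MaxPool2x2())
        c_prev = c
    layers.append(GlobalAvgPool())
    trunk = Sequential(layers)

    n_blocks = len(cfg["channels"])
    # trunk split at the midpoint of its conv blocks (3 layers per block)
    split = (n_blocks // 2) * 3

    head_seq = Sequential(
        [
            Dense(backbone.feature_width, head.hidden_width, rng=layer_rngs[-1]),
            ReLU(),
            Dense(head.hidden_width, head.output_width, zero_init=True),
        ]
    )
    return CountRegressor(
        trunk,
        head_seq,
        backbone_spec=backbone,
        head_spec=head,
        normalization=normalization,
        cam_layer_index=last_relu,
        section_split=split,
    )


def predict_counts(model: CountRegressor, images, batch_size: int = 128) -> np.ndarray:
    """Module-level alias for :meth:`CountRegressor.predict`."""
    return model.predict(images, batch_size=batch_size)
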