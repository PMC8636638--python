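import numpy as np
import pytest
from skimage.measure import label as _cc_label

from countreg import CountDataset, DotSceneSpec, LabelledImage


def component_count(pixels: np.ndarray, threshold: float = 0.35) -> int:
    """Independent count oracle: 4-connected components of the thresholded render."""
    return int(_cc_label(pixels > threshold, connectivity=1).max())


def dummy_dataset(labels, prefix: str = "img", **kwargs) -> CountDataset:
    """Dataset of 1-pixel images — for label/split machinery tests."""
    px = np.zeros((1, 1), dtype=np.float32)
    return CountDataset(
        [
            LabelledImage(pixels=px, label=int(l), id=f"{prefix}-{i:06d}", **kwargs)
            for i, l in enumerate(labels)
        ]
    )


@pytest.fixture
def noiseless_dot_spec() -> DotSceneSpec:
    """Dot scenes with no texture, no lighting jitter and no distractors,
    so thresholded connected components recover the label exactly."""
    return DotSceneSpec(
        background_texture_amplitude=0.0,
        lighting_jitter=(1.0, 1.0),
        distractor_count_range=(0, 0),
        overlap_allowed=False,
    )


@pytest.fixture
def small_dot_spec() -> DotSceneSpec:
    """32x32 low-count scenes for fast end-to-end pipeline tests."""
    return DotSceneSpec(image_height=32, image_width=32, count_range=(0, 8))
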