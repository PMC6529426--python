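from __future__ import annotations

import numpy as np
import pytest

from thtquant.io import ScalarImage, extract_green
from thtquant.synthetic import SceneSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def noise_free_spec():
    """Isolated in-range cells on a zero background: exact ground truth."""
    return SceneSpec(
        n_cells=10,
        fraction_small=0.0,
        fraction_edge=0.0,
        fraction_clump=0.0,
        pixel_sigma=0.0,
        background_mean=0.0,
        background_sigma=0.0,
        seed=42,
    )


def scene_green(img) -> ScalarImage:
    return extract_green(img)


def label_map_from_boxes(shape, boxes) -> np.ndarray:
    """Build a label map from (label, row_slice, col_slice) rectangles."""
    labels = np.zeros(shape, dtype=np.int32)
    for lab, rs, cs in boxes:
        labels[rs, cs] = lab
    return labels
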