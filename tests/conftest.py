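import numpy as np
import pytest

from spgfp import SceneParams, SegConfig, generate_scene, segment_cells


SMALL = dict(shape=(10, 128, 128), n_cells=4)


@pytest.fixture(scope="session")
def small_scene():
    """A compact noisy two-channel scene with ground truth."""
    params = SceneParams(seed=42, **SMALL)
    stack, truth = generate_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_labels(small_scene):
    _, stack, _ = small_scene
    return segment_cells(stack, SegConfig())


def best_iou_label(labels2d: np.ndarray, gt_mask: np.ndarray) -> tuple[int, float]:
    """Label with the highest IoU against a ground-truth 2D mask."""
    best, best_label = 0.0, 0
    for lab in range(1, int(labels2d.max()) + 1):
        m = labels2d == lab
        inter = int((m & gt_mask).sum())
        union = int((m | gt_mask).sum())
        iou = inter / union if union else 0.0
        if iou > best:
            best, best_label = iou, lab
    return best_label, best
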