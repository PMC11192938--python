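import heapq

import numpy as np
import pytest

from spgfp import SceneParams, SegConfig, generate_scene, segment_cells
from spgfp.io import ImageStack
from spgfp.segmentation import (
    random_walker_segment,
    sum_project,
    watershed_split,
)
from conftest import best_iou_label


# ---------------------------------------------------------------------------
# z-sum projection


def test_single_slice_projection_is_the_slice():
    data = np.random.default_rng(0).integers(0, 99, (1, 1, 1, 4, 5))
    stack = ImageStack(data)
    assert np.array_equal(sum_project(stack, 0)[0], data[0, 0, 0])


def test_all_zero_projection():
    stack = ImageStack(np.zeros((1, 2, 3, 4, 4), dtype=np.uint16))
    assert not sum_project(stack, 1).any()


def test_projection_matches_loop_oracle():
    rng = np.random.default_rng(1)
    data = rng.integers(0, 1000, (2, 2, 3, 4, 4))
    stack = ImageStack(data)
    proj = sum_project(stack, 1)
    for t in range(2):
        for y in range(4):
            for x in range(4):
                assert proj[t, y, x] == sum(int(data[t, 1, z, y, x]) for z in range(3))


def test_projection_bad_channel():
    with pytest.raises(ValueError):
        sum_project(ImageStack(np.zeros((1, 1, 1, 2, 2))), 3)


# ---------------------------------------------------------------------------
# random walker


def _dense_walker_oracle(image, seeds, beta):
    """Brute-force solve of the walker linear system with dense algebra."""
    img = image.astype(float)
    sigma = img.std() or 1.0
    ny, nx = img.shape
    n = ny * nx
    W = np.zeros((n, n))
    for y in range(ny):
        for x in range(nx):
            i = y * nx + x
            for dy, dx in ((1, 0), (0, 1)):
                v, u = y + dy, x + dx
                if v < ny and u < nx:
                    j = v * nx + u
                    w = np.exp(-beta * (img[y, x] - img[v, u]) ** 2 / sigma**2) + 1e-6
                    W[i, j] = W[j, i] = w
    L = np.diag(W.sum(axis=1)) - W
    s = seeds.ravel()
    unk = s == 0
    m = (s[~unk] == 2).astype(float)
    prob = np.zeros(n)
    prob[~unk] = m
    if unk.any():
        A = L[np.ix_(unk, unk)]
        b = -L[np.ix_(unk, ~unk)] @ m
        prob[unk] = np.linalg.solve(A, b)
    return prob.reshape(image.shape)


def test_fully_seeded_image_returns_seeds():
    img = np.zeros((3, 3))
    seeds = np.array([[1, 1, 2], [1, 2, 2], [1, 1, 2]], dtype=np.int8)
    prob, mask = random_walker_segment(img, seeds, beta=10)
    assert np.array_equal(mask, seeds == 2)
    assert np.array_equal(prob, (seeds == 2).astype(float))


def test_constant_image_symmetric_seeds_split_at_midline():
    img = np.full((5, 6), 7.0)
    seeds = np.zeros((5, 6), dtype=np.int8)
    seeds[2, 1] = 1
    seeds[2, 4] = 2
    _, mask = random_walker_segment(img, seeds, beta=100)
    assert not mask[:, :3].any()
    assert mask[:, 3:].all()


@pytest.mark.parametrize("shape,seed", [((5, 5), 0), ((7, 6), 1), ((4, 7), 2)])
def test_walker_matches_dense_oracle(shape, seed):
    rng = np.random.default_rng(seed)
    img = rng.random(shape) * 10
    seeds = np.zeros(shape, dtype=np.int8)
    seeds[0, 0] = 1
    seeds[-1, -1] = 2
    seeds[rng.integers(0, shape[0]), rng.integers(0, shape[1])] = 1
    beta = 50.0
    prob, _ = random_walker_segment(img, seeds, beta=beta)
    oracle = _dense_walker_oracle(img, seeds, beta)
    assert np.max(np.abs(prob - oracle)) < 1e-8


def test_walker_probabilities_normalized_and_bounded():
    rng = np.random.default_rng(3)
    img = rng.random((9, 9))
    seeds = np.zeros((9, 9), dtype=np.int8)
    seeds[0, :] = 1
    seeds[4, 4] = 2
    prob, _ = random_walker_segment(img, seeds, beta=80)
    assert np.all(prob >= -1e-6) and np.all(prob <= 1 + 1e-6)
    # two-class probabilities sum to one per pixel by construction
    assert np.allclose(prob + (1 - prob), 1.0, atol=1e-6)


def test_walker_invariant_to_intensity_offset():
    rng = np.random.default_rng(4)
    img = rng.random((8, 8)) * 5
    seeds = np.zeros((8, 8), dtype=np.int8)
    seeds[0, 0] = 1
    seeds[7, 7] = 2
    p1, _ = random_walker_segment(img, seeds, beta=60)
    p2, _ = random_walker_segment(img + 123.4, seeds, beta=60)
    assert np.allclose(p1, p2, atol=1e-9)


def test_walker_requires_both_seed_classes():
    with pytest.raises(ValueError):
        random_walker_segment(np.zeros((3, 3)), np.zeros((3, 3), dtype=np.int8))


# ---------------------------------------------------------------------------
# watershed


def _geodesic_oracle(elevation, markers, mask):
    """Independent topographic-distance assignment: per-marker shortest
    total-ascent paths by exhaustive relaxation, then argmin with ties to
    the smaller marker index."""
    ny, nx = elevation.shape
    ids = np.unique(markers[markers > 0])
    best_cost = {}
    for lab in ids:
        cost = np.full((ny, nx), np.inf)
        cost[(markers == lab) & mask] = 0.0
        # Bellman-Ford-style sweeps until the fixpoint: independent of the
        # priority-queue implementation under test
        changed = True
        while changed:
            changed = False
            for y in range(ny):
                for x in range(nx):
                    if not mask[y, x]:
                        continue
                    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        v, u = y + dy, x + dx
                        if 0 <= v < ny and 0 <= u < nx and mask[v, u]:
                            nc = cost[v, u] + max(elevation[y, x] - elevation[v, u], 0.0)
                            if nc < cost[y, x] - 1e-12:
                                cost[y, x] = nc
                                changed = True
        best_cost[lab] = cost
    out = np.zeros((ny, nx), dtype=np.int32)
    for y, x in zip(*np.nonzero(mask)):
        costs = [(best_cost[lab][y, x], lab) for lab in ids]
        c, lab = min(costs)
        if np.isfinite(c):
            out[y, x] = lab
    return out


def _disk(shape, cy, cx, r):
    yy, xx = np.indices(shape)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def test_single_disk_single_label():
    mask = _disk((20, 20), 10, 10, 6)
    labels = watershed_split(mask)
    assert labels.max() == 1
    assert np.array_equal(labels > 0, mask)


def test_empty_mask_empty_labels():
    assert watershed_split(np.zeros((5, 5), dtype=bool)).max() == 0


def test_two_overlapping_disks_match_geodesic_oracle():
    from scipy import ndimage as ndi
    from skimage.morphology import local_maxima

    mask = _disk((24, 32), 12, 10, 8) | _disk((24, 32), 12, 21, 8)
    labels = watershed_split(mask, marker_smooth_sigma=1.0)
    assert labels.max() == 2
    # rebuild the same markers and elevation, assign by brute force
    edt = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(edt, 1.0)
    peaks = local_maxima(smoothed, connectivity=2) & mask
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    oracle = _geodesic_oracle(-edt, markers, mask)
    assert np.array_equal(labels, oracle)


def test_watershed_partitions_mask_exactly():
    rng = np.random.default_rng(5)
    blob = rng.random((30, 30)) > 0.4
    from scipy import ndimage as ndi
    blob = ndi.binary_closing(blob)
    labels = watershed_split(blob)
    assert np.array_equal(labels > 0, blob)
    ids = np.unique(labels)
    assert np.array_equal(ids[ids > 0], np.arange(1, labels.max() + 1))


# ---------------------------------------------------------------------------
# full segmentation


def test_background_only_scene_gives_zero_labels():
    stack, _ = generate_scene(SceneParams(n_cells=0, noise=False, shape=(6, 48, 48)))
    labels = segment_cells(stack, SegConfig())
    assert labels.max() == 0  # warning, not an exception


def test_small_scene_cells_recovered(small_scene, small_labels):
    _, _, truth = small_scene
    labels = small_labels[0]
    assert int(labels.max()) == truth.n_cells
    for i in range(truth.n_cells):
        _, iou = best_iou_label(labels, truth.cell_masks[i].any(axis=0))
        assert iou >= 0.8


def test_touching_pair_split_into_two():
    params = SceneParams(seed=40, shape=(10, 128, 128), n_cells=4, touching_pair=True)
    stack, truth = generate_scene(params)
    labels = segment_cells(stack, SegConfig())[0]
    assert int(labels.max()) == truth.n_cells


def test_segment_cells_deterministic(small_scene, small_labels):
    _, stack, _ = small_scene
    again = segment_cells(stack, SegConfig())
    assert np.array_equal(again, small_labels)
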