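import dataclasses
import math

import numpy as np
import pytest

from spgfp import (
    CytometryParams,
    SceneParams,
    TimeLapseParams,
    generate_cytometry,
    generate_scene,
    generate_timelapse,
)
from spgfp.synthetic import PlacementError

SMALL = dict(shape=(10, 128, 128), n_cells=3)


def test_background_only_scene_is_exactly_flat():
    params = SceneParams(n_cells=0, noise=False, shape=(6, 32, 32))
    stack, truth = generate_scene(params)
    assert truth.n_cells == 0
    assert np.all(stack.data == params.background)


def test_outside_cell_equals_background_without_blur_or_noise():
    params = SceneParams(n_cells=1, noise=False, blur_sigma_um=0.0, seed=1, **{
        "shape": (10, 96, 96)})
    stack, truth = generate_scene(params)
    outside = ~truth.cell_masks[0]
    for ch in range(2):
        assert np.all(stack.data[0, ch][outside] == params.background)


def test_mito_mask_matches_brute_force_rerasterization():
    """Tube voxels equal an independent re-rasterization of the skeleton."""
    params = SceneParams(seed=3, noise=False, **SMALL)
    _, truth = generate_scene(params)
    dx, dy, dz = params.voxel_size
    spacing = np.array([dz, dy, dx])
    for i in range(truth.n_cells):
        sk = truth.skeletons[i]
        # brute force: physical distance from every voxel centre to every
        # skeleton voxel centre
        coords = np.indices(params.shape).reshape(3, -1).T * spacing
        sk_um = sk * spacing
        d2 = ((coords[:, None, :] - sk_um[None, :, :]) ** 2).sum(axis=2)
        within = (d2.min(axis=1) <= params.mito_tube_radius_um**2).reshape(params.shape)
        expected = within & truth.cell_masks[i]
        assert np.array_equal(expected, truth.mito_masks[i])


def test_same_seed_scene_is_bit_identical():
    params = SceneParams(seed=7, **SMALL)
    s1, t1 = generate_scene(params)
    s2, t2 = generate_scene(params)
    assert np.array_equal(s1.data, s2.data)
    assert np.array_equal(t1.g, t2.g)
    assert np.array_equal(t1.mito_labels, t2.mito_labels)


def test_mito_contained_in_cells_and_cells_disjoint():
    params = SceneParams(seed=11, **SMALL)
    _, truth = generate_scene(params)
    total = np.zeros(params.shape, dtype=int)
    for i in range(truth.n_cells):
        assert not np.any(truth.mito_masks[i] & ~truth.cell_masks[i])
        total += truth.cell_masks[i]
    assert total.max() <= 1  # non-touching scene: no overlap anywhere


def test_noiseless_reporter_scales_linearly_with_g():
    base = SceneParams(seed=5, noise=False, **SMALL)
    doubled = dataclasses.replace(base, reporter_log_mean=base.reporter_log_mean + math.log(2))
    s1, t1 = generate_scene(base)
    s2, t2 = generate_scene(doubled)
    assert np.allclose(t2.g, 2 * t1.g)
    sig1 = s1.data[0, 1] - base.background
    sig2 = s2.data[0, 1] - base.background
    assert np.allclose(sig2, 2 * sig1, atol=1e-9)


def test_control_condition_frames_identical_without_noise():
    params = SceneParams(seed=2, noise=False, **SMALL)
    tl = TimeLapseParams(n_frames=4)
    stack, _ = generate_timelapse(params, tl, condition="control")
    for t in range(1, 4):
        assert np.array_equal(stack.data[t], stack.data[0])


def test_cccp_frame_ratio_matches_closed_form():
    """Reporter decay per frame equals 2**(-dt/t_half) exactly (noise off)."""
    params = SceneParams(seed=2, noise=False, **SMALL)
    tl = TimeLapseParams(n_frames=3, interval_min=5.0)
    stack, truth = generate_timelapse(params, tl, condition="CCCP")
    expected = 2.0 ** (-tl.interval_min / tl.half_life_min["CCCP"])
    sig0 = stack.data[0, 1] - params.background
    sig1 = stack.data[1, 1] - params.background
    mito = truth.mito_labels > 0
    assert np.allclose(sig1[mito] / sig0[mito], expected, rtol=1e-12)
    # marker channel stays constant
    assert np.array_equal(stack.data[0, 0], stack.data[1, 0])
    # ground-truth trajectories obey the decay law exactly
    ratio = truth.trajectories[:, 1:] / truth.trajectories[:, :-1]
    assert np.allclose(ratio, expected, rtol=1e-12)


def test_same_seed_timelapse_is_bit_identical():
    params = SceneParams(seed=9, **SMALL)
    tl = TimeLapseParams(n_frames=3)
    s1, _ = generate_timelapse(params, tl, "CCCP")
    s2, _ = generate_timelapse(params, tl, "CCCP")
    assert np.array_equal(s1.data, s2.data)


def test_unknown_condition_rejected():
    with pytest.raises(ValueError, match="half-life"):
        generate_timelapse(SceneParams(**SMALL), TimeLapseParams(), "heat-shock")


def test_placement_failure_raises():
    params = SceneParams(shape=(10, 64, 64), n_cells=30, max_place_tries=20)
    with pytest.raises(PlacementError):
        generate_scene(params)


def test_touching_pair_masks_touch():
    params = SceneParams(seed=4, touching_pair=True, **SMALL)
    _, truth = generate_scene(params)
    from scipy import ndimage as ndi
    a = ndi.binary_dilation(truth.cell_masks[0])
    assert np.any(a & truth.cell_masks[1])


def test_cytometry_zero_positive_fraction_all_negative():
    values, labels = generate_cytometry(CytometryParams(n_events=500, positive_fraction=0.0))
    assert len(values) == 500
    assert np.all(labels == 0)


def test_cytometry_empty():
    values, labels = generate_cytometry(CytometryParams(n_events=0))
    assert values.size == 0 and labels.size == 0


def test_cytometry_component_moments_match_lognormal():
    """Sample moments of each component within 3 SE of closed forms."""
    p = CytometryParams(n_events=100_000, seed=13)
    values, labels = generate_cytometry(p)
    for comp, mu, sig in ((0, p.negative_log_mean, p.negative_log_sigma),
                          (1, p.positive_log_mean, p.positive_log_sigma)):
        v = values[labels == comp]
        n = len(v)
        mean = math.exp(mu + sig**2 / 2)
        var = (math.exp(sig**2) - 1) * math.exp(2 * mu + sig**2)
        se_mean = math.sqrt(var / n)
        assert abs(v.mean() - mean) < 3 * se_mean
        # SE of the sample variance via the 4th central moment of a log-normal
        m4 = (np.mean((v - v.mean()) ** 4))
        se_var = math.sqrt(max(m4 - var**2, 0) / n)
        assert abs(v.var(ddof=1) - var) < 3 * se_var
    # expected positive count
    npos = int((labels == 1).sum())
    se = math.sqrt(p.n_events * p.positive_fraction * (1 - p.positive_fraction))
    assert abs(npos - p.n_events * p.positive_fraction) < 3 * se


def test_cytometry_same_seed_identical():
    p = CytometryParams(n_events=1000, seed=21)
    v1, l1 = generate_cytometry(p)
    v2, l2 = generate_cytometry(p)
    assert np.array_equal(v1, v2) and np.array_equal(l1, l2)


@pytest.mark.parametrize("bad", [
    dict(n_cells=-1),
    dict(voxel_size=(0.1, 0.1, 0.0)),
    dict(cell_radius_um=(2.0, 1.0)),
    dict(mito_tube_radius_um=0.0),
])
def test_invalid_scene_params_rejected(bad):
    with pytest.raises(ValueError):
        SceneParams(**bad).validate()
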