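"""Ground-truth-annotated synthetic data for the split-GFP import pipeline.

Three generators emulate the data the analysis consumes:

* :func:`generate_scene` — a two-channel 3D confocal stack of yeast-like
  cells.  Channel 0 carries a mitochondrial marker (mCherry-like) confined
  to tubular networks inside each cell; channel 1 carries the split-GFP
  reporter, restricted to the mitochondrial voxels at a per-cell level
  ``g_i`` plus a small cytosolic fraction.
* :func:`generate_timelapse` — the same scene replayed over frames with a
  condition-dependent exponential decay of the reporter (import block by
  CCCP reveals intramitochondrial degradation; the control condition does
  not decay).
* :func:`generate_cytometry` — a two-component log-normal event mixture
  with a specified positive fraction, for negative-control gating.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` per call, so identical parameters give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .io import ImageStack

__all__ = [
    "SceneParams",
    "TimeLapseParams",
    "CytometryParams",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "generate_timelapse",
    "generate_cytometry",
    "rasterize_tube",
]


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class SceneParams:
    """Geometry, intensity and noise model of one synthetic scene.

    Lengths are micrometres, intensities arbitrary camera units.  The
    default grid is 20 x 256 x 256 voxels at 0.1 x 0.1 x 0.5 µm — a yeast
    field small enough for seconds-scale tests.  Yeast cells are 3–5 µm in
    diameter, hence the 1.5–2.5 µm radius range.
    """

    shape: tuple[int, int, int] = (20, 256, 256)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.5)  # dx, dy, dz µm
    n_cells: int = 10
    cell_radius_um: tuple[float, float] = (1.5, 2.5)
    eccentricity: float = 0.1  # per-axis radius jitter, fraction of radius
    mito_tube_radius_um: float = 0.25
    # tube length scales with cell volume (mitochondrial content tracks
    # cell size); 0.75 µm per µm³ gives ~25 µm of tube in a 2 µm cell
    mito_density_um_per_um3: float = 0.75
    reporter_log_mean: float = math.log(300.0)  # g_i ~ LogNormal(µ, σ)
    reporter_log_sigma: float = 0.4
    marker_level: float = 200.0
    cytosol_fraction: float = 0.05  # of g_i, spread over the whole cell
    background: float = 10.0
    blur_sigma_um: float = 0.15  # isotropic PSF proxy
    poisson_gain: float = 1.0
    read_noise_sigma: float = 2.0
    noise: bool = True
    touching_pair: bool = False
    max_place_tries: int = 500
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be 3 positive axis lengths (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.cell_radius_um
        if not (0 < lo <= hi):
            raise ValueError("cell radius range must be 0 < lo <= hi")
        for name in ("mito_tube_radius_um", "mito_density_um_per_um3",
                     "marker_level", "poisson_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.touching_pair and self.n_cells < 2:
            raise ValueError("touching_pair requires n_cells >= 2")


@dataclass(frozen=True)
class TimeLapseParams:
    """Frame count, interval and per-condition clearance half-lives.

    The default conditions mirror the import-block experiment: under CCCP
    the mitochondrial reporter clears with a 6.9 min half-life; under the
    control condition the signal is steady (infinite half-life).  Frames
    are 5 min apart by default.
    """

    n_frames: int = 13
    interval_min: float = 5.0
    half_life_min: dict = field(
        default_factory=lambda: {"CCCP": 6.9, "control": math.inf}
    )
    bleach_per_frame: float = 1.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        for cond, t_half in self.half_life_min.items():
            if not (t_half > 0):
                raise ValueError(f"half-life for {cond!r} must be > 0 (or inf)")
        if not (0 < self.bleach_per_frame <= 1):
            raise ValueError("bleach_per_frame must be in (0, 1]")


@dataclass(frozen=True)
class CytometryParams:
    """Two-component log-normal event mixture.

    The default positive fraction is 0.268; components are well separated
    (negatives around 100 a.u., positives around 2000 a.u.) so a
    negative-control gate recovers the fraction.
    """

    n_events: int = 50_000
    positive_fraction: float = 0.268
    negative_log_mean: float = math.log(100.0)
    negative_log_sigma: float = 0.4
    positive_log_mean: float = math.log(2000.0)
    positive_log_sigma: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.negative_log_sigma <= 0 or self.positive_log_sigma <= 0:
            raise ValueError("component log-sigmas must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth used to validate every downstream stage.

    ``cell_labels`` / ``mito_labels`` are (z, y, x) integer maps (0 =
    background, cell ids 1..N).  ``cell_masks`` keeps the per-cell boolean
    volumes (these may overlap when ``touching_pair`` is set; the label
    maps resolve overlap first-come).  ``skeletons`` holds each cell's
    mitochondrial tube skeleton as an (n, 3) integer voxel-index array —
    enough to re-rasterize the tubes independently.

    ``mito_median_ref`` is the per-cell ground truth for what the 2D
    quantification measures: the median of the noiseless, blurred,
    background-free reporter z-sum over the cell's true mitochondrial
    columns.  Estimates from the noisy pipeline are validated against it
    (the raw level ``g`` is a per-voxel quantity and differs from the
    z-sum by each cell's tube-crossing geometry).
    """

    cell_labels: np.ndarray
    mito_labels: np.ndarray
    cell_masks: list[np.ndarray]
    mito_masks: list[np.ndarray]
    skeletons: list[np.ndarray]
    g: np.ndarray  # per-cell reporter level
    centers_um: np.ndarray  # (n, 3) z, y, x
    radii_um: np.ndarray  # (n, 3) semi-axes z, y, x
    # time-lapse truth (filled by generate_timelapse)
    mito_median_ref: np.ndarray | None = None  # noiseless measured level
    times_min: np.ndarray | None = None
    decay_rate_per_min: np.ndarray | None = None  # k_i = ln2 / t_half
    half_life_min: float | None = None
    trajectories: np.ndarray | None = None  # (n_cells, n_frames) g_i * 2^(-t/t_half)

    @property
    def n_cells(self) -> int:
        return len(self.cell_masks)


# ---------------------------------------------------------------------------
# geometry helpers


def _voxel_coords(shape, voxel_size):
    """Physical (z, y, x) coordinate vectors of voxel centres, in µm."""
    dx, dy, dz = voxel_size
    nz, ny, nx = shape
    return (
        np.arange(nz) * dz,
        np.arange(ny) * dy,
        np.arange(nx) * dx,
    )


def _ellipsoid_mask(shape, voxel_size, center, radii):
    zc, yc, xc = _voxel_coords(shape, voxel_size)
    dz = (zc - center[0]) / radii[0]
    dy = (yc - center[1]) / radii[1]
    dx = (xc - center[2]) / radii[2]
    return (
        dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    ) <= 1.0


def _place_cells(params: SceneParams, rng: np.random.Generator):
    """Sample non-overlapping ellipsoids fully inside the volume."""
    dx, dy, dz = params.voxel_size
    extent = np.array(
        [(params.shape[0] - 1) * dz, (params.shape[1] - 1) * dy, (params.shape[2] - 1) * dx]
    )
    lo, hi = params.cell_radius_um
    centers: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    # clearance between non-touching cells; generous enough that the PSF
    # cannot fuse neighbours (touching cases come from the explicit flag)
    margin = 0.8  # µm

    def sample_radii():
        r = rng.uniform(lo, hi)
        ecc = rng.uniform(1 - params.eccentricity, 1 + params.eccentricity, size=3)
        rad = r * ecc
        # keep the axial semi-axis inside a shallow z range
        rad[0] = min(rad[0], extent[0] / 2 * 0.95)
        return rad

    def sample_center(rad):
        lo_c = rad.copy()
        hi_c = extent - rad
        if np.any(hi_c < lo_c):
            raise PlacementError("cell does not fit inside the volume")
        c = rng.uniform(lo_c, hi_c)
        # cells on a pad form a monolayer: centres sit near the mid-plane
        # (small axial jitter), so cells never stack along z
        z_mid = extent[0] / 2
        c[0] = np.clip(z_mid + rng.uniform(-0.3, 0.3), lo_c[0], hi_c[0])
        return c

    def overlaps(c, r, skip=()):
        # lateral separation is what matters in a monolayer (and in the
        # z-sum projection the analysis works on)
        for j, (cj, rj) in enumerate(zip(centers, radii)):
            if j in skip:
                continue
            if np.linalg.norm(c[1:] - cj[1:]) < r[1:].max() + rj[1:].max() + margin:
                return True
        return False

    n_placed_normally = params.n_cells - (2 if params.touching_pair else 0)
    if params.touching_pair:
        # one pair at sub-diameter centre distance, so their masks touch;
        # the surface distance uses the ellipsoid radius along the line
        # between the centres
        for _ in range(params.max_place_tries):
            r1, r2 = sample_radii(), sample_radii()
            c1 = sample_center(r1)
            theta = rng.uniform(0, 2 * math.pi)
            direction = np.array([0.0, math.sin(theta), math.cos(theta)])
            rad_along = [1.0 / math.sqrt(np.sum(direction**2 / r**2)) for r in (r1, r2)]
            c2 = c1 + direction * 0.92 * sum(rad_along)
            if np.all(c2 >= r2) and np.all(c2 <= extent - r2):
                centers.extend([c1, c2])
                radii.extend([r1, r2])
                break
        else:
            raise PlacementError("could not place the touching pair")
    for _ in range(n_placed_normally):
        for _ in range(params.max_place_tries):
            r = sample_radii()
            c = sample_center(r)
            if not overlaps(c, r):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping cells"
            )
    if centers:
        return np.array(centers), np.array(radii)
    return np.zeros((0, 3)), np.zeros((0, 3))


def _walk_skeleton(params: SceneParams, center, radii, rng: np.random.Generator):
    """Persistent random-walk tube skeleton inside a shrunk ellipsoid.

    Tube length is proportional to the cell's volume (constant
    mitochondrial content per unit volume).  Returns unique voxel indices
    (n, 3) visited by the walk, sampled every 0.1 µm of arc length.
    """
    step = 0.1
    volume = 4.0 / 3.0 * math.pi * float(np.prod(radii))
    length = params.mito_density_um_per_um3 * volume
    n_steps = max(int(round(length / step)), 1)
    # keep the tube surface a little under the membrane (cortical network,
    # but inset as in projections of real cells)
    clearance = params.mito_tube_radius_um + 0.15
    shrink = np.clip(1.0 - clearance / radii, 0.3, None)
    inner = radii * shrink

    def inside(p):
        return np.sum(((p - center) / inner) ** 2) <= 1.0

    pos = center.copy()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [pos.copy()]
    for _ in range(n_steps):
        for _ in range(25):
            cand_dir = direction + 0.4 * rng.normal(size=3)
            cand_dir /= np.linalg.norm(cand_dir)
            cand = pos + step * cand_dir
            if inside(cand):
                pos, direction = cand, cand_dir
                break
        else:
            # fall back: step toward the centre
            direction = center - pos
            n = np.linalg.norm(direction)
            direction = direction / n if n > 0 else np.array([0.0, 0.0, 1.0])
            pos = pos + step * direction
        pts.append(pos.copy())
    pts_arr = np.array(pts)
    dx, dy, dz = params.voxel_size
    idx = np.round(pts_arr / np.array([dz, dy, dx])).astype(int)
    idx = np.clip(idx, 0, np.array(params.shape) - 1)
    return np.unique(idx, axis=0)


def rasterize_tube(skeleton_idx: np.ndarray, shape, voxel_size, tube_radius_um: float):
    """Voxels whose centre lies within ``tube_radius_um`` of a skeleton voxel.

    Distances are Euclidean in physical units.  This is the rendering rule
    for mitochondrial tubes; tests re-derive it by brute force.
    """
    if len(skeleton_idx) == 0:
        return np.zeros(shape, dtype=bool)
    dx, dy, dz = voxel_size
    sk = np.zeros(shape, dtype=bool)
    sk[tuple(skeleton_idx.T)] = True
    pad = np.ceil(tube_radius_um / np.array([dz, dy, dx])).astype(int) + 1
    lo = np.maximum(skeleton_idx.min(axis=0) - pad, 0)
    hi = np.minimum(skeleton_idx.max(axis=0) + pad + 1, np.array(shape))
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    dist = ndi.distance_transform_edt(~sk[box], sampling=(dz, dy, dx))
    out = np.zeros(shape, dtype=bool)
    out[box] = dist <= tube_radius_um
    return out


# ---------------------------------------------------------------------------
# rendering


def _render_clean(params: SceneParams, truth: GroundTruth):
    """Noiseless, pre-background marker and reporter volumes."""
    shape = params.shape
    marker = np.zeros(shape, dtype=float)
    reporter = np.zeros(shape, dtype=float)
    for i in range(truth.n_cells):
        g = truth.g[i]
        marker[truth.mito_masks[i]] = params.marker_level
        reporter[truth.cell_masks[i]] += params.cytosol_fraction * g
        reporter[truth.mito_masks[i]] += g
    return marker, reporter


def _blur(vol: np.ndarray, params: SceneParams) -> np.ndarray:
    if params.blur_sigma_um <= 0:
        return vol
    dx, dy, dz = params.voxel_size
    sigma = (params.blur_sigma_um / dz, params.blur_sigma_um / dy, params.blur_sigma_um / dx)
    return ndi.gaussian_filter(vol, sigma=sigma, mode="reflect")


def _mito_median_refs(
    truth: GroundTruth, marker_blurred: np.ndarray, reporter_blurred: np.ndarray,
    threshold_fraction: float = 0.05,
) -> np.ndarray:
    """Noiseless per-cell reference for the 2D mitochondrial median.

    Applies the same operational definition as the quantification stage —
    marker z-sum thresholded at a fraction of the per-cell maximum, median
    reporter z-sum within the resulting mask — to the noiseless, blurred,
    background-free rendering on the true cell masks.  Estimates from the
    noisy pipeline are compared against this estimand.
    """
    marker_proj = marker_blurred.sum(axis=0)
    reporter_proj = reporter_blurred.sum(axis=0)
    refs = np.full(truth.n_cells, np.nan)
    for i in range(truth.n_cells):
        cols = truth.cell_masks[i].any(axis=0)
        if not cols.any():
            continue
        peak = marker_proj[cols].max()
        if peak <= 0:
            continue
        mito_cols = cols & (marker_proj >= threshold_fraction * peak)
        refs[i] = float(np.median(reporter_proj[mito_cols]))
    return refs


def _camera(vol: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on (signal + background), then Gaussian read noise."""
    if not params.noise:
        return vol
    lam = np.clip(vol, 0, None) * params.poisson_gain
    out = rng.poisson(lam).astype(float) / params.poisson_gain
    if params.read_noise_sigma > 0:
        out += rng.normal(0.0, params.read_noise_sigma, size=vol.shape)
    return np.clip(out, 0, None)


def _build_truth(params: SceneParams, rng: np.random.Generator) -> GroundTruth:
    centers, radii = _place_cells(params, rng)
    n = len(centers)
    g = np.exp(rng.normal(params.reporter_log_mean, params.reporter_log_sigma, size=n))
    cell_masks, mito_masks, skeletons = [], [], []
    cell_labels = np.zeros(params.shape, dtype=np.int32)
    mito_labels = np.zeros(params.shape, dtype=np.int32)
    for i in range(n):
        cmask = _ellipsoid_mask(params.shape, params.voxel_size, centers[i], radii[i])
        sk = _walk_skeleton(params, centers[i], radii[i], rng)
        mmask = rasterize_tube(sk, params.shape, params.voxel_size, params.mito_tube_radius_um)
        mmask &= cmask  # containment invariant
        cell_masks.append(cmask)
        mito_masks.append(mmask)
        skeletons.append(sk)
        cell_labels[cmask & (cell_labels == 0)] = i + 1
        mito_labels[mmask & (mito_labels == 0)] = i + 1
    return GroundTruth(
        cell_labels=cell_labels,
        mito_labels=mito_labels,
        cell_masks=cell_masks,
        mito_masks=mito_masks,
        skeletons=skeletons,
        g=g,
        centers_um=centers,
        radii_um=radii,
    )


def generate_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Render one two-channel 3D scene with ground truth.

    Channel 0 is the mitochondrial marker, channel 1 the reporter.  The
    clean signal is blurred, offset by the background, then passed through
    the Poisson + Gaussian camera model (unless ``noise`` is off).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = _build_truth(params, rng)
    marker, reporter = _render_clean(params, truth)
    marker = _blur(marker, params)
    reporter = _blur(reporter, params)
    truth.mito_median_ref = _mito_median_refs(truth, marker, reporter)
    marker = _camera(marker + params.background, params, rng)
    reporter = _camera(reporter + params.background, params, rng)
    data = np.stack([marker, reporter])[np.newaxis]  # (1, 2, z, y, x)
    stack = ImageStack(
        data=data,
        voxel_size=params.voxel_size,
        channel_names=("marker", "reporter"),
    )
    return stack, truth


def generate_timelapse(
    scene_params: SceneParams,
    tl_params: TimeLapseParams,
    condition: str = "CCCP",
) -> tuple[ImageStack, GroundTruth]:
    """Replay a scene over time with exponential reporter clearance.

    Geometry and the marker channel are constant; the reporter signal of
    cell *i* at frame *t* is ``g_i * 2**(-t*dt/t_half)`` before noise.
    Photobleaching, if enabled, multiplies both channels by a per-frame
    scalar.
    """
    scene_params.validate()
    tl_params.validate()
    if condition not in tl_params.half_life_min:
        raise ValueError(
            f"condition {condition!r} has no half-life; known: {sorted(tl_params.half_life_min)}"
        )
    t_half = tl_params.half_life_min[condition]
    rng = np.random.default_rng(scene_params.seed)
    truth = _build_truth(scene_params, rng)
    marker, reporter = _render_clean(scene_params, truth)
    marker = _blur(marker, scene_params)
    reporter = _blur(reporter, scene_params)
    truth.mito_median_ref = _mito_median_refs(truth, marker, reporter)

    times = np.arange(tl_params.n_frames) * tl_params.interval_min
    decay = np.power(2.0, -times / t_half) if math.isfinite(t_half) else np.ones_like(times)
    frames = []
    for t in range(tl_params.n_frames):
        bleach = tl_params.bleach_per_frame ** t
        m = bleach * marker + scene_params.background
        r = bleach * decay[t] * reporter + scene_params.background
        m = _camera(m, scene_params, rng)
        r = _camera(r, scene_params, rng)
        frames.append(np.stack([m, r]))
    stack = ImageStack(
        data=np.stack(frames),
        voxel_size=scene_params.voxel_size,
        frame_interval_min=tl_params.interval_min,
        channel_names=("marker", "reporter"),
    )
    k = math.log(2.0) / t_half if math.isfinite(t_half) else 0.0
    truth.times_min = times
    truth.half_life_min = t_half
    truth.decay_rate_per_min = np.full(truth.n_cells, k)
    truth.trajectories = truth.g[:, None] * decay[None, :]
    return stack, truth


def generate_cytometry(params: CytometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Draw a two-component log-normal event mixture.

    Returns ``(values, labels)`` with ``labels[i] = 1`` for events drawn
    from the positive component, 0 for the negative component.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    labels = (rng.random(n) < params.positive_fraction).astype(np.int8)
    neg = rng.lognormal(params.negative_log_mean, params.negative_log_sigma, size=n)
    pos = rng.lognormal(params.positive_log_mean, params.positive_log_sigma, size=n)
    values = np.where(labels == 1, pos, neg)
    return values, labels
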