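"""Cell tracking and exponential clearance kinetics.

After an import block (CCCP) the mitochondrial reporter signal decays as
it is degraded inside mitochondria.  Cells immobilised on an agar pad are
near-stationary, so tracking reduces to greedy intersection-over-union
matching of segmentation labels between consecutive frames.  Each cell's
median mitochondrial reporter trajectory is then fit with a first-order
clearance model with plateau,

    I(t) = I_inf + (I0 - I_inf) * exp(-k t),    k >= 0,

whose half-life is t_half = ln 2 / k.  The plateau term absorbs the
non-clearing background the reporter does not decay to zero through; a
pure exponential (I_inf = 0) is available by option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import ImageStack
from .quantification import QuantConfig, per_cell_quantify
from .segmentation import sum_project

__all__ = [
    "Track",
    "Trajectory",
    "DecayFit",
    "track_cells",
    "measure_trajectories",
    "fit_decay",
    "summarize_condition",
]

MIN_FIT_POINTS = 4
NON_DECAY_FRACTION = 0.05  # fitted decline below 5% of I0 => not decaying


@dataclass
class Track:
    """A cell followed through consecutive frames."""

    track_id: int
    frames: list[int]
    labels: list[int]  # per-frame segmentation label
    complete: bool  # spans every frame of the movie


@dataclass
class Trajectory:
    """Median mitochondrial reporter intensity of one cell over time."""

    cell_id: int
    condition: str
    times_min: np.ndarray
    values: np.ndarray
    complete: bool = True

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DecayFit:
    """Fitted clearance parameters for one trajectory."""

    cell_id: int
    i0: float
    i_inf: float
    k_per_min: float
    half_life_min: float  # NaN unless k > 0 and the fit converged
    r_squared: float
    converged: bool
    non_decaying: bool


# ---------------------------------------------------------------------------
# tracking


def iou_matrix(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """IoU between every label of two equal-shape label maps.

    Entry ``[i, j]`` is the IoU of label ``i+1`` in A with ``j+1`` in B.
    """
    na = int(labels_a.max())
    nb = int(labels_b.max())
    if na == 0 or nb == 0:
        return np.zeros((na, nb))
    both = (labels_a > 0) & (labels_b > 0)
    pair = labels_a[both].astype(np.int64) * (nb + 1) + labels_b[both]
    counts = np.bincount(pair, minlength=(na + 1) * (nb + 1))
    inter = counts.reshape(na + 1, nb + 1)[1:, 1:].astype(float)
    area_a = np.bincount(labels_a.ravel(), minlength=na + 1)[1:]
    area_b = np.bincount(labels_b.ravel(), minlength=nb + 1)[1:]
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def _greedy_match(iou: np.ndarray, min_iou: float) -> dict[int, int]:
    """Greedy 1:1 matching by descending IoU; deterministic tie-break."""
    order = []
    na, nb = iou.shape
    for i in range(na):
        for j in range(nb):
            if iou[i, j] >= min_iou:
                order.append((-iou[i, j], i, j))
    order.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    match: dict[int, int] = {}
    for _, i, j in order:
        if i not in used_a and j not in used_b:
            match[i + 1] = j + 1
            used_a.add(i)
            used_b.add(j)
    return match


def track_cells(label_maps: np.ndarray, min_iou: float = 0.5) -> list[Track]:
    """Link labels across frames by greedy IoU matching.

    Matches below ``min_iou`` are rejected; an unmatched cell ends its
    track (flagged incomplete).  Labels appearing mid-movie start new
    (incomplete) tracks.
    """
    label_maps = np.asarray(label_maps)
    if label_maps.ndim != 3:
        raise ValueError("label_maps must be (time, y, x)")
    n_frames = label_maps.shape[0]
    tracks: list[Track] = []
    open_by_label: dict[int, Track] = {}
    for lab in range(1, int(label_maps[0].max()) + 1):
        tr = Track(track_id=len(tracks), frames=[0], labels=[lab], complete=True)
        tracks.append(tr)
        open_by_label[lab] = tr
    for t in range(1, n_frames):
        match = _greedy_match(iou_matrix(label_maps[t - 1], label_maps[t]), min_iou)
        next_open: dict[int, Track] = {}
        for lab_prev, tr in open_by_label.items():
            if lab_prev in match:
                lab_new = match[lab_prev]
                tr.frames.append(t)
                tr.labels.append(lab_new)
                next_open[lab_new] = tr
            else:
                tr.complete = False
        for lab_new in range(1, int(label_maps[t].max()) + 1):
            if lab_new not in next_open:
                tr = Track(track_id=len(tracks), frames=[t], labels=[lab_new], complete=False)
                tracks.append(tr)
                next_open[lab_new] = tr
        open_by_label = next_open
    for tr in tracks:
        if len(tr.frames) < n_frames:
            tr.complete = False
    return tracks


def measure_trajectories(
    stack: ImageStack,
    label_maps: np.ndarray,
    tracks: list[Track] | None = None,
    quant_config: QuantConfig | None = None,
    marker_channel: int = 0,
    reporter_channel: int = 1,
    condition: str = "",
) -> list[Trajectory]:
    """Median mitochondrial reporter per tracked cell per frame.

    Frames where a cell is missing or its mitochondrial mask is empty are
    dropped from that cell's trajectory (fits use available points only).
    """
    if tracks is None:
        tracks = track_cells(label_maps)
    marker_proj = sum_project(stack, marker_channel)
    reporter_proj = sum_project(stack, reporter_channel)
    times = stack.times_min()
    values: dict[tuple[int, int], float] = {}
    for t in range(stack.nt):
        for rec in per_cell_quantify(
            label_maps[t], marker_proj[t], reporter_proj[t], quant_config, frame=t
        ):
            if not rec.empty_mito:
                values[(t, rec.cell_id)] = rec.mito_reporter_median
    out: list[Trajectory] = []
    for tr in tracks:
        pts = [
            (times[f], values[(f, lab)])
            for f, lab in zip(tr.frames, tr.labels)
            if (f, lab) in values
        ]
        if not pts:
            continue
        tt, vv = zip(*pts)
        out.append(
            Trajectory(
                cell_id=tr.track_id,
                condition=condition,
                times_min=np.array(tt),
                values=np.array(vv),
                complete=tr.complete and len(pts) == stack.nt,
            )
        )
    return out


# ---------------------------------------------------------------------------
# decay fitting


def _initial_guess(t: np.ndarray, v: np.ndarray, plateau: bool):
    i_inf0 = float(v.min()) if plateau else 0.0
    i00 = float(v[0])
    y = v - i_inf0
    good = y > max(y.max(), 0) * 1e-6
    if good.sum() >= 2:
        slope = np.polyfit(t[good], np.log(y[good]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1e-3
    return i00, i_inf0, k0


def fit_decay(
    trajectory: Trajectory, plateau: bool = True
) -> DecayFit:
    """Least-squares exponential clearance fit of one trajectory.

    Requires at least 4 points.  Initialisation: plateau from the minimum
    value, amplitude from the first value, rate from a log-linear
    regression on the plateau-subtracted values.  When the fitted decline
    over the observed window is below 5% of the initial level the
    trajectory is flagged non-decaying and the rate reported as zero.
    """
    t = trajectory.times_min
    v = trajectory.values
    keep = np.isfinite(v)
    t, v = t[keep], v[keep]
    if len(v) < MIN_FIT_POINTS:
        raise ValueError(f"need >= {MIN_FIT_POINTS} points to fit, got {len(v)}")

    i00, i_inf0, k0 = _initial_guess(t, v, plateau)

    if plateau:
        def resid(p):
            i0, i_inf, k = p
            return i_inf + (i0 - i_inf) * np.exp(-k * (t - t[0])) - v
        x0 = [i00, i_inf0, k0]
        lb = [0.0, 0.0, 0.0]
        ub = [np.inf, np.inf, np.inf]
    else:
        def resid(p):
            i0, k = p
            return i0 * np.exp(-k * (t - t[0])) - v
        x0 = [i00, k0]
        lb = [0.0, 0.0]
        ub = [np.inf, np.inf]

    res = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if plateau:
        i0, i_inf, k = (float(x) for x in res.x)
    else:
        i0, k = (float(x) for x in res.x)
        i_inf = 0.0
    converged = bool(res.success)

    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    span = t[-1] - t[0]
    decline = (i0 - i_inf) * (1.0 - math.exp(-k * span))
    non_decaying = not (decline > NON_DECAY_FRACTION * i0) if i0 > 0 else True
    if non_decaying:
        k = 0.0
    half_life = math.log(2.0) / k if (k > 0 and converged) else float("nan")
    return DecayFit(
        cell_id=trajectory.cell_id,
        i0=i0,
        i_inf=i_inf,
        k_per_min=k,
        half_life_min=half_life,
        r_squared=r2,
        converged=converged,
        non_decaying=non_decaying,
    )


def summarize_condition(
    trajectories: list[Trajectory], condition: str | None = None
) -> pd.DataFrame:
    """Per-timepoint mean ± SEM across cells of one condition.

    Returns a frame with columns ``time_min, n, mean, sem``; the SEM is
    NaN where only one cell contributes.
    """
    if condition is not None:
        trajectories = [tr for tr in trajectories if tr.condition == condition]
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    rows: dict[float, list[float]] = {}
    for tr in trajectories:
        for time, value in zip(tr.times_min, tr.values):
            rows.setdefault(float(time), []).append(float(value))
    out = []
    for time in sorted(rows):
        vals = np.array(rows[time])
        n = len(vals)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        out.append({"time_min": time, "n": n, "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(out, columns=["time_min", "n", "mean", "sem"])
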