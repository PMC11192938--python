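"""Image and table I/O with a canonical in-memory axis convention.

Every stack in this package is a 5-axis array ordered ``(time, channel, z,
y, x)`` with physical voxel sizes in micrometres and an optional frame
interval in minutes.  Voxel indices are 0-based and a voxel's value is the
sample at the voxel centre, located at ``index * spacing``.  TIFF files are
written as plain multi-page TIFF; metadata that TIFF tags cannot carry
(axis order, voxel size, frame interval, channel names) lives in a JSON
sidecar next to the image file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

CANONICAL_AXES = "TCZYX"

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_records",
    "read_records",
    "sidecar_path",
]


@dataclass
class ImageStack:
    """A 5-axis intensity array with physical calibration.

    Parameters
    ----------
    data
        Array with canonical axes ``(time, channel, z, y, x)``.  Lower
        dimensional input is expanded on the left.
    voxel_size
        ``(dx, dy, dz)`` in micrometres.
    frame_interval_min
        Time between frames in minutes, or ``None`` for single time points.
    channel_names
        Optional channel labels, one per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval_min: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim > 5:
            raise ValueError(f"stack has {arr.ndim} axes; at most 5 supported")
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        self.data = arr
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.frame_interval_min is not None and self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.channel_names is not None:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.nc:
                raise ValueError("one channel name per channel required")

    @property
    def nt(self) -> int:
        return self.data.shape[0]

    @property
    def nc(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in cubic micrometres (dx * dy * dz)."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (frame index * interval)."""
        dt = self.frame_interval_min if self.frame_interval_min is not None else 1.0
        return np.arange(self.nt, dtype=float) * dt


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".json")


def _canonicalize_axes(axes: str, ndim: int) -> str:
    """Map an axis string onto canonical letters, filling unknowns."""
    axes = axes.upper().replace("S", "C")
    if len(axes) != ndim:
        raise ValueError(f"axis string {axes!r} does not match array with {ndim} axes")
    # Unknown letters (Q, I, ...) become the unused canonical axes, Z first:
    # a bare 3D stack is most plausibly a z-series.
    out: list[str] = []
    for a in axes:
        if a in CANONICAL_AXES and a not in out:
            out.append(a)
        else:
            for cand in "ZTC":
                if cand not in axes and cand not in out:
                    out.append(cand)
                    break
            else:
                raise ValueError(f"cannot interpret axis string {axes!r}")
    if len(set(out)) != len(out):
        raise ValueError(f"duplicate axes in {axes!r}")
    return "".join(out)


def _to_canonical(data: np.ndarray, axes: str) -> np.ndarray:
    axes = _canonicalize_axes(axes, data.ndim)
    missing = [a for a in CANONICAL_AXES if a not in axes]
    data = data.reshape((1,) * len(missing) + data.shape)
    axes = "".join(missing) + axes
    order = [axes.index(a) for a in CANONICAL_AXES]
    return np.transpose(data, order)


def read_stack(path: str | Path, axes: str | None = None) -> ImageStack:
    """Read a multi-page TIFF into a canonical :class:`ImageStack`.

    Axis order is taken from (in priority order) the ``axes`` argument, the
    JSON sidecar, or the TIFF series metadata.  Missing calibration falls
    back to 1 µm voxels with a logged warning.
    """
    path = Path(path)
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
    ax = axes or meta.get("axes") or file_axes
    if len(ax) != data.ndim:
        raise ValueError(
            f"declared axes {ax!r} inconsistent with data of shape {data.shape}"
        )
    data = _to_canonical(data, ax)
    if "voxel_size_um" in meta:
        voxel = tuple(meta["voxel_size_um"])
    else:
        voxel = (1.0, 1.0, 1.0)
        logger.warning("%s: no voxel size metadata, defaulting to 1 um", path)
    return ImageStack(
        data=data,
        voxel_size=voxel,  # type: ignore[arg-type]
        frame_interval_min=meta.get("frame_interval_min"),
        channel_names=tuple(meta["channel_names"]) if meta.get("channel_names") else None,
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus JSON sidecar. Lossless for ints."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data
    if data.dtype == np.float64:
        # TIFF readers are happier with float32; float64 is kept if exact
        # round trip would be lost.
        f32 = data.astype(np.float32)
        if np.array_equal(f32.astype(np.float64), data):
            data = f32
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "axes": CANONICAL_AXES,
        "voxel_size_um": list(stack.voxel_size),
        "frame_interval_min": stack.frame_interval_min,
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _record_columns(kind) -> list[str]:
    if not (is_dataclass(kind) and isinstance(kind, type)):
        raise TypeError("kind must be a dataclass type")
    return [f.name for f in fields(kind)]


def write_records(records: Iterable, path: str | Path, kind=None) -> Path:
    """Write per-cell / per-fit records to CSV with a stable row order.

    ``records`` is a sequence of dataclass instances (or dicts).  Rows are
    sorted by ``(frame, cell_id)`` when those columns exist, then by all
    columns, so repeated runs produce byte-identical files.  ``kind`` (a
    dataclass type) supplies the header for an empty record list.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    if rows:
        df = pd.DataFrame(rows)
    elif kind is not None:
        df = pd.DataFrame(columns=_record_columns(kind))
    else:
        df = pd.DataFrame()
    sort_cols = [c for c in ("frame", "cell_id", "track_id", "piece_id") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
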