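"""Per-cell reporter quantification inside mitochondria, and mito volumes.

The core statistic of the pipeline: for each segmented cell, the marker
channel is thresholded at a fraction *f* (default 5%) of its per-cell
maximum to delineate mitochondria, and the median reporter intensity
within that mask is recorded.  The same *f*-of-max rule applied to the 3D
marker volume yields mitochondrial pieces (connected components) whose
volume is voxel count times the physical voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "QuantConfig",
    "CellRecord",
    "MitoPiece",
    "per_cell_quantify",
    "mito_volumes",
    "mito_mask_for_cell",
]


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    ``threshold_fraction``: mitochondrial threshold as a fraction of the
    maximal marker value (0.05 = 5%).  ``threshold_scope`` applies the
    fraction to each cell's own maximum (``"cell"``, the default reading
    of "for each cell ... 5% of maximal value") or to the global image
    maximum (``"global"``).  ``statistic`` is the per-cell intensity
    summary; ``connectivity`` (26 or 6) defines 3D mitochondrial pieces.
    ``background_subtract`` subtracts the median of the unlabelled region
    from both channels before any statistic.
    """

    threshold_fraction: float = 0.05
    threshold_scope: str = "cell"
    statistic: str = "median"
    connectivity: int = 26
    background_subtract: bool = False

    def validate(self) -> None:
        if not (0.0 < self.threshold_fraction < 1.0):
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.threshold_scope not in ("cell", "global"):
            raise ValueError("threshold_scope must be 'cell' or 'global'")
        if self.statistic not in ("median", "mean"):
            raise ValueError("statistic must be 'median' or 'mean'")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class CellRecord:
    """One cell's quantification in one frame."""

    frame: int
    cell_id: int
    cell_area_px: int
    marker_median: float
    reporter_median: float
    mito_threshold: float
    mito_area_px: int
    mito_reporter_median: float  # NaN when the mito mask is empty
    empty_mito: bool


@dataclass
class MitoPiece:
    """One connected mitochondrial component of one cell."""

    cell_id: int
    piece_id: int
    voxels: int
    volume_um3: float


def _stat(values: np.ndarray, statistic: str) -> float:
    if values.size == 0:
        return float("nan")
    return float(np.median(values) if statistic == "median" else np.mean(values))


def _check_labels(label_map: np.ndarray) -> np.ndarray:
    ids = np.unique(label_map)
    ids = ids[ids > 0]
    if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
        raise ValueError("label map must have contiguous labels 1..N")
    return ids


def mito_mask_for_cell(
    marker: np.ndarray, cell_mask: np.ndarray, config: QuantConfig
) -> tuple[np.ndarray, float]:
    """Apply the f-of-max rule inside one cell; returns (mask, threshold).

    The threshold is ``f * max(marker in cell)`` (or the global maximum
    under global scope); mitochondrial pixels are those with marker values
    at or above the threshold.  An all-zero cell yields an empty mask.
    """
    ref = marker[cell_mask].max() if config.threshold_scope == "cell" else marker.max()
    thr = config.threshold_fraction * float(ref)
    if ref <= 0:
        return np.zeros_like(cell_mask), thr
    return cell_mask & (marker >= thr), thr


def per_cell_quantify(
    label_map: np.ndarray,
    marker2d: np.ndarray,
    reporter2d: np.ndarray,
    config: QuantConfig | None = None,
    frame: int = 0,
) -> list[CellRecord]:
    """Quantify every cell of a single-frame label map.

    For each label: cell-wide marker and reporter statistics, the
    marker-derived mitochondrial mask, and the reporter statistic within
    mitochondria.  Cells whose mitochondrial mask is empty are flagged and
    carry NaN for the mito statistic.
    """
    config = config or QuantConfig()
    config.validate()
    label_map = np.asarray(label_map)
    marker = np.asarray(marker2d, dtype=float)
    reporter = np.asarray(reporter2d, dtype=float)
    if not (label_map.shape == marker.shape == reporter.shape):
        raise ValueError("label map and projections must share shape")
    ids = _check_labels(label_map)
    if config.background_subtract:
        bg = label_map == 0
        if bg.any():
            marker = marker - np.median(marker[bg])
            reporter = reporter - np.median(reporter[bg])
    records: list[CellRecord] = []
    for cid in ids.tolist():
        cell = label_map == cid
        mito, thr = mito_mask_for_cell(marker, cell, config)
        n_mito = int(mito.sum())
        records.append(
            CellRecord(
                frame=frame,
                cell_id=int(cid),
                cell_area_px=int(cell.sum()),
                marker_median=_stat(marker[cell], config.statistic),
                reporter_median=_stat(reporter[cell], config.statistic),
                mito_threshold=thr,
                mito_area_px=n_mito,
                mito_reporter_median=_stat(reporter[mito], config.statistic)
                if n_mito
                else float("nan"),
                empty_mito=n_mito == 0,
            )
        )
    return records


def _structure(connectivity: int) -> np.ndarray:
    return (
        np.ones((3, 3, 3), dtype=int)
        if connectivity == 26
        else ndi.generate_binary_structure(3, 1)
    )


def mito_volumes(
    marker3d: np.ndarray,
    cell_labels3d: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: QuantConfig | None = None,
) -> tuple[list[MitoPiece], dict[int, float]]:
    """Mitochondrial pieces and per-cell total volumes from a 3D marker.

    The f-of-max rule is applied per cell to the raw 3D marker; connected
    components under the configured connectivity are the pieces.  Volume
    is voxel count times dx*dy*dz (µm³).  Returns the piece list and a
    mapping cell id -> total volume (0.0 for cells with no mitochondrial
    voxels).
    """
    config = config or QuantConfig()
    config.validate()
    marker3d = np.asarray(marker3d, dtype=float)
    cell_labels3d = np.asarray(cell_labels3d)
    if marker3d.shape != cell_labels3d.shape:
        raise ValueError("marker and cell masks must share shape")
    dx, dy, dz = voxel_size
    vox_vol = dx * dy * dz
    ids = _check_labels(cell_labels3d)
    pieces: list[MitoPiece] = []
    totals: dict[int, float] = {}
    for cid in ids.tolist():
        cell = cell_labels3d == cid
        mito, _ = mito_mask_for_cell(marker3d, cell, config)
        lab, n = ndi.label(mito, structure=_structure(config.connectivity))
        total = 0.0
        for pid in range(1, n + 1):
            nvox = int((lab == pid).sum())
            vol = nvox * vox_vol
            pieces.append(MitoPiece(cell_id=int(cid), piece_id=pid, voxels=nvox, volume_um3=vol))
            total += vol
        totals[int(cid)] = total
    return pieces, totals
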