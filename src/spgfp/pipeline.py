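"""Configurable end-to-end runs: simulate -> segment -> quantify (+ kinetics).

A run is described by one YAML mapping (see ``default_config``).  Every
stage writes its artefacts into the output directory and a manifest
records the config hash, seed and library versions, so a run can be
reproduced exactly from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cytometry import compute_gate, fraction_positive
from .io import ImageStack, read_stack, write_records, write_stack
from .kinetics import Trajectory, fit_decay, measure_trajectories, summarize_condition, track_cells
from .quantification import CellRecord, MitoPiece, QuantConfig, mito_volumes, per_cell_quantify
from .segmentation import SegConfig, segment_cells, sum_project
from .synthetic import (
    CytometryParams,
    SceneParams,
    TimeLapseParams,
    generate_cytometry,
    generate_scene,
    generate_timelapse,
)

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "load_config", "default_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


def default_config() -> dict:
    return {
        "stages": ["simulate", "segment", "quantify"],
        "seed": 0,
        "condition": "CCCP",
        "scene": {},  # SceneParams overrides
        "timelapse": None,  # TimeLapseParams overrides; None = single scene
        "segmentation": {},  # SegConfig overrides
        "quantification": {},  # QuantConfig overrides
        "cytometry": None,  # CytometryParams overrides
        "gate_quantile": 0.995,
        "paths": {},  # inputs for non-simulation runs: stack, labels
    }


def _build(cls, overrides, where: str):
    overrides = overrides or {}
    names = {f.name for f in dataclasses.fields(cls)}
    for key in overrides:
        if key not in names:
            raise ConfigError(f"{where}.{key}: unknown field")
    try:
        obj = cls(**overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"{key}: unknown config key")
        cfg[key] = value
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_manifest(cfg: dict, out_dir: Path) -> None:
    import scipy
    import skimage

    manifest = {
        "config": cfg,
        "config_sha256_16": _config_hash(cfg),
        "seed": cfg.get("seed"),
        "versions": {
            "spgfp": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _labels_to_stack(labels: np.ndarray, template: ImageStack) -> ImageStack:
    return ImageStack(
        data=labels[:, np.newaxis, np.newaxis].astype(np.int32),
        voxel_size=template.voxel_size,
        frame_interval_min=template.frame_interval_min,
    )


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory.

    Stage names: ``simulate`` (scene or time lapse, per config),
    ``segment``, ``quantify``, ``kinetics``, ``cytometry``.  Later stages
    consume the in-memory products of earlier ones, or the files named
    under ``paths`` when run standalone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages") or []
    known = {"simulate", "segment", "quantify", "kinetics", "cytometry"}
    for st in stages:
        if st not in known:
            raise ConfigError(f"stages: unknown stage {st!r}")

    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: must be an integer")

    scene_over = dict(cfg.get("scene") or {})
    scene_over.setdefault("seed", seed)
    stack: ImageStack | None = None
    labels: np.ndarray | None = None

    if "simulate" in stages:
        scene_params = _build(SceneParams, scene_over, "scene")
        if cfg.get("timelapse") is not None:
            tl_params = _build(TimeLapseParams, cfg["timelapse"], "timelapse")
            stack, truth = generate_timelapse(scene_params, tl_params, cfg.get("condition", "CCCP"))
        else:
            stack, truth = generate_scene(scene_params)
        write_stack(stack, out_dir / "stack.tif")
        truth_stack = ImageStack(
            data=np.stack([truth.cell_labels, truth.mito_labels])[np.newaxis],
            voxel_size=scene_params.voxel_size,
        )
        write_stack(truth_stack, out_dir / "truth_labels.tif")
        pd_truth = [
            {"cell_id": i + 1, "g": float(truth.g[i])} for i in range(truth.n_cells)
        ]
        write_records(pd_truth, out_dir / "truth_cells.csv")

    if stack is None and any(s in stages for s in ("segment", "quantify", "kinetics")):
        stack_path = (cfg.get("paths") or {}).get("stack")
        if not stack_path:
            raise ConfigError("paths.stack: required when not simulating")
        stack = read_stack(stack_path)

    if "segment" in stages:
        seg_config = _build(SegConfig, cfg.get("segmentation"), "segmentation")
        labels = segment_cells(stack, seg_config)
        write_stack(_labels_to_stack(labels, stack), out_dir / "labels.tif")

    if labels is None and any(s in stages for s in ("quantify", "kinetics")):
        labels_path = (cfg.get("paths") or {}).get("labels")
        if not labels_path:
            raise ConfigError("paths.labels: required when not segmenting")
        labels = read_stack(labels_path).data[:, 0, 0].astype(np.int32)

    quant_config = _build(QuantConfig, cfg.get("quantification"), "quantification")

    if "quantify" in stages:
        marker = sum_project(stack, 0)
        reporter = sum_project(stack, 1)
        records: list[CellRecord] = []
        for t in range(stack.nt):
            records.extend(
                per_cell_quantify(labels[t], marker[t], reporter[t], quant_config, frame=t)
            )
        write_records(records, out_dir / "cells.csv", kind=CellRecord)
        # 3D mitochondrial volumes from frame 0, cells extruded through z
        cells3d = np.broadcast_to(labels[0], stack.data.shape[2:]).copy()
        pieces, totals = mito_volumes(stack.data[0, 0], cells3d, stack.voxel_size, quant_config)
        write_records(pieces, out_dir / "mito_pieces.csv", kind=MitoPiece)
        write_records(
            [{"cell_id": cid, "total_volume_um3": vol} for cid, vol in sorted(totals.items())],
            out_dir / "mito_totals.csv",
        )

    if "kinetics" in stages:
        tracks = track_cells(labels)
        trajs = measure_trajectories(
            stack, labels, tracks, quant_config, condition=cfg.get("condition", "")
        )
        fits = []
        for tr in trajs:
            if np.isfinite(tr.values).sum() >= 4:
                fits.append(fit_decay(tr))
        write_records(fits, out_dir / "fits.csv")
        traj_rows = [
            {
                "cell_id": tr.cell_id,
                "time_min": float(t),
                "value": float(v),
                "condition": tr.condition,
                "complete": tr.complete,
            }
            for tr in trajs
            for t, v in zip(tr.times_min, tr.values)
        ]
        write_records(traj_rows, out_dir / "trajectories.csv")
        if trajs:
            summarize_condition(trajs).to_csv(out_dir / "condition_summary.csv", index=False)

    if "cytometry" in stages:
        cyt_over = dict(cfg.get("cytometry") or {})
        cyt_over.setdefault("seed", seed)
        cyt_params = _build(CytometryParams, cyt_over, "cytometry")
        values, comp = generate_cytometry(cyt_params)
        ctrl_params = dataclasses.replace(
            cyt_params, positive_fraction=0.0, seed=cyt_params.seed + 1
        )
        control, _ = generate_cytometry(ctrl_params)
        gate = compute_gate(control, cfg.get("gate_quantile", 0.995))
        result = fraction_positive(values, gate.tau)
        (out_dir / "gate.json").write_text(
            json.dumps(
                {
                    "tau": gate.tau,
                    "quantile": gate.quantile,
                    "n_control": gate.n_control,
                    "fraction_positive": result.fraction,
                    "percent_positive": result.percent,
                    "n_events": result.n,
                },
                indent=1,
                sort_keys=True,
            )
        )

    _write_manifest(cfg, out_dir)
    return out_dir
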