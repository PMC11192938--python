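#!/usr/bin/env python
"""Segment the default scenes and validate per-cell quantification.

For a set of synthetic scenes: segment cells on the reporter z-sum
projection (random walker + watershed), quantify the median reporter
intensity inside each cell's mitochondria (marker thresholded at 5% of
the per-cell maximum), and compare against the generator's ground truth:
cell counts, per-cell outline IoU, and recovery of the noiseless
reference levels.

Writes results/segmentation_metrics.csv (one row per cell) and prints
the summary statistics.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spgfp import QuantConfig, SceneParams, SegConfig, generate_scene, per_cell_quantify, segment_cells
from spgfp.segmentation import sum_project

ROOT = Path(__file__).resolve().parents[1]


def best_iou(labels, gt):
    best, best_lab = 0.0, 0
    for lab in range(1, int(labels.max()) + 1):
        m = labels == lab
        iou = (m & gt).sum() / (m | gt).sum()
        if iou > best:
            best, best_lab = iou, lab
    return best_lab, best


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-scenes", type=int, default=5)
    args = ap.parse_args()

    rows = []
    for k in range(args.n_scenes):
        seed = args.seed + k
        stack, truth = generate_scene(SceneParams(seed=seed))
        labels = segment_cells(stack, SegConfig())[0]
        marker = sum_project(stack, 0)[0]
        reporter = sum_project(stack, 1)[0]
        recs = {
            r.cell_id: r
            for r in per_cell_quantify(
                labels, marker, reporter, QuantConfig(background_subtract=True)
            )
        }
        for i in range(truth.n_cells):
            lab, iou = best_iou(labels, truth.cell_masks[i].any(axis=0))
            rec = recs.get(lab)
            rows.append({
                "scene_seed": seed,
                "cell_id": i + 1,
                "n_labels": int(labels.max()),
                "matched_label": lab,
                "iou": iou,
                "g": truth.g[i],
                "mito_median_ref": truth.mito_median_ref[i],
                "mito_median_est": rec.mito_reporter_median if rec else np.nan,
            })

    df = pd.DataFrame(rows)
    out = ROOT / "results" / "segmentation_metrics.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False)

    counts_ok = (df.groupby("scene_seed").n_labels.first()
                 == df.groupby("scene_seed").cell_id.count()).all()
    ok = df.dropna(subset=["mito_median_est"])
    r_ref = np.corrcoef(ok.mito_median_est, ok.mito_median_ref)[0, 1]
    r_g = np.corrcoef(ok.mito_median_est, ok.g)[0, 1]
    bias = np.median(ok.mito_median_est / ok.mito_median_ref) - 1

    print(f"{args.n_scenes} scenes, {len(df)} cells")
    print(f"cell counts exact in every scene: {counts_ok}")
    print(f"outline IoU: min {df.iou.min():.3f}, mean {df.iou.mean():.3f}")
    print(f"mito median vs noiseless reference: r = {r_ref:.3f}, "
          f"median relative bias = {bias:+.1%}")
    print(f"mito median vs raw per-voxel level g: r = {r_g:.3f} "
          f"(geometry-confounded, shown for context)")
    print(f"per-cell table -> {out}")


if __name__ == "__main__":
    main()
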