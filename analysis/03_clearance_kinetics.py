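#!/usr/bin/env python
"""Fit mitochondrial reporter clearance from synthetic time lapses.

Generates a CCCP-condition time lapse (import blocked, reporter degraded
inside mitochondria; generator half-life 6.9 min) and a control time
lapse (steady signal), runs the full pipeline — marker-channel
segmentation, per-cell mito medians, IoU tracking, exponential fits with
plateau — and reports the recovered half-lives and per-timepoint
mean ± SEM condition summaries.

Writes results/kinetics_fits.csv and results/kinetics_summary.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spgfp import QuantConfig, SceneParams, SegConfig, TimeLapseParams, generate_timelapse
from spgfp.kinetics import fit_decay, measure_trajectories, summarize_condition, track_cells
from spgfp.segmentation import segment_cells
from spgfp.workflows import derive_seed

ROOT = Path(__file__).resolve().parents[1]


def run_condition(condition: str, seed: int, noise: bool):
    scene = SceneParams(seed=seed, noise=noise)
    stack, truth = generate_timelapse(scene, TimeLapseParams(), condition)
    labels = segment_cells(stack, SegConfig(channel=0))
    tracks = track_cells(labels)
    trajs = measure_trajectories(stack, labels, tracks, QuantConfig(), condition=condition)
    fits = [fit_decay(tr) for tr in trajs if np.isfinite(tr.values).sum() >= 4]
    return truth, trajs, fits


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--noise", action="store_true",
                    help="enable the camera noise model (default: noiseless)")
    args = ap.parse_args()

    fit_rows, summaries = [], []
    for condition in ("CCCP", "control"):
        truth, trajs, fits = run_condition(condition, derive_seed(args.seed, 1), args.noise)
        for f in fits:
            fit_rows.append({
                "condition": condition,
                "cell_id": f.cell_id,
                "k_per_min": f.k_per_min,
                "half_life_min": f.half_life_min,
                "r_squared": f.r_squared,
                "non_decaying": f.non_decaying,
            })
        s = summarize_condition(trajs)
        s.insert(0, "condition", condition)
        summaries.append(s)

        hl = [f.half_life_min for f in fits if np.isfinite(f.half_life_min)]
        nd = sum(f.non_decaying for f in fits)
        if condition == "CCCP":
            print(f"CCCP: {len(fits)} cells fitted, median half-life "
                  f"{np.median(hl):.3f} min (generator truth {truth.half_life_min} min)")
        else:
            print(f"control: {len(fits)} cells fitted, {nd} flagged non-decaying "
                  f"(signal steady, as generated)")

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    pd.DataFrame(fit_rows).to_csv(out_dir / "kinetics_fits.csv", index=False)
    pd.concat(summaries).to_csv(out_dir / "kinetics_summary.csv", index=False)
    print(f"fits -> {out_dir / 'kinetics_fits.csv'}")
    print(f"mean +/- SEM per timepoint -> {out_dir / 'kinetics_summary.csv'}")


if __name__ == "__main__":
    main()
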