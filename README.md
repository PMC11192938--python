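# spgfp — split-GFP mitochondrial import quantification

Quantitative pipeline for split-GFP (spGFP) reporters of mitochondrial
protein import. In this assay the GFP₁₋₁₀ fragment is targeted to the
mitochondrial matrix and GFP₁₁ is fused to a cargo protein (for example
α-synuclein); fluorescence reconstitutes only when the cargo enters the
matrix, so the spGFP signal inside mitochondria reports import, and its
decay after an import block (CCCP) reports intramitochondrial
degradation.

The package implements the measurements such experiments need, each as a
tested library function:

* **Segmentation** of yeast cells from two-channel confocal z-stacks:
  z-sum projection, seeded random-walker foreground extraction (edge
  weights `w_ij = exp(-β (I_i - I_j)² / σ_I²)` on the 4-connected pixel
  lattice), and topographic-distance watershed to separate adjacent
  cells.
* **Per-cell quantification**: the mitochondrial mask is the marker
  (mCherry) channel thresholded at a fraction *f* = 0.05 of the per-cell
  maximum; the statistic is the median reporter intensity within that
  mask. Mitochondrial piece volumes are connected components of the 3D
  mask times the voxel volume `dx·dy·dz`.
* **Clearance kinetics**: greedy IoU tracking of cells across a 5-min
  time lapse and least-squares fits of
  `I(t) = I∞ + (I0 − I∞)·e^(−kt)`, with half-life `t½ = ln 2 / k`.
* **Cytometry gating**: positivity threshold at a high quantile
  (default 0.995) of a negative-control sample; the positive fraction is
  the share of events strictly above the gate.
* **Synthetic data**: a ground-truth-annotated generator for all of the
  above — 3D yeast-like cells with tubular mitochondrial networks,
  reporter restricted to mitochondria with per-cell levels
  `g_i ~ LogNormal`, Poisson + Gaussian camera noise, exponential
  reporter decay over time lapses, and two-component cytometry mixtures
  — so the whole pipeline is testable without microscopy data.

## Worked example

```sh
python analysis/03_clearance_kinetics.py --seed 0
```

prints

```
CCCP: 10 cells fitted, median half-life 6.900 min (generator truth 6.9 min)
control: 10 cells fitted, 10 flagged non-decaying (signal steady, as generated)
```

Under CCCP the generator decays each cell's mitochondrial reporter with
a 6.9-minute half-life; the pipeline — segmentation on the constant
marker channel, per-frame mito medians, tracking, exponential fit —
recovers that value per cell. The control condition does not decay and
every cell is correctly flagged non-decaying. Similarly,

```sh
python analysis/04_cytometry_gating.py --seed 0
```

```
gate at tau = 277.0 a.u. (0.995 quantile of 50000 control events)
recovered positive: 27.06% of 50000 events (generating fraction 26.8%, this sample's truth 26.72%)
```

the negative-control gate recovers the generating 26.8% positive
fraction; the ~0.3-point excess is the designed 0.5% false-positive
allowance of the 0.995-quantile gate acting on the negative majority.

The other drivers (`analysis/01_simulate.py`,
`analysis/02_segment_quantify.py`) render scenes and validate
segmentation and intensity recovery against ground truth; all tables
land in `results/`.

A `spgfp` command exposes the same stages for file-based runs
(`simulate`, `segment`, `quantify`, `timelapse`, `gate`, and `run` for a
config-driven pipeline with a reproducibility manifest); images are
multi-page TIFF with a JSON sidecar, tables are CSV.

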