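# Methods

## Problem and measurement model

A split-GFP import reporter fluoresces only after its GFP₁₁-tagged cargo
reaches the mitochondrial matrix, where matrix-targeted GFP₁₋₁₀ resides.
Two quantities carry the biology:

1. the **median reporter intensity inside mitochondria, per cell** —
   how much cargo is inside the organelle; and
2. its **clearance rate after an import block** — how fast the imported
   cargo is degraded. With import stopped (CCCP collapses the membrane
   potential), the mitochondrial signal follows first-order decay
   `I(t) = I∞ + (I0 − I∞)·e^(−kt)` with half-life `t½ = ln2/k`.

Flow cytometry gives a third, population-level readout: the fraction of
cells whose reporter fluorescence exceeds a gate placed on a
reporter-free negative control.

All image quantities are computed on z-sum projections of two-channel
(mitochondrial marker + reporter) confocal stacks, except mitochondrial
volume, which uses the raw 3D marker. Axes are canonically
`(time, channel, z, y, x)`; physical units are micrometres and minutes.

## Pipeline

**Segmentation** (`spgfp.segmentation`). The projection of the chosen
channel (reporter by default) is smoothed (Gaussian, σ = 2 px). Seeds
are set relative to the background level: with `m` the median and
`s = 1.4826·MAD` the robust noise scale of the smoothed projection,
pixels ≤ `m + 2s` seed the background and pixels ≥ `m + 5s` seed cells.
A seeded random walker on the 4-connected lattice with edge weights
`exp(-β (ΔI)²/σ_I²)` (β = 50, σ_I the image standard deviation, plus a
1e-6 conductance floor that keeps the linear system well conditioned)
yields per-pixel foreground probabilities; the mask is probability
> 0.5. The sparse system is solved by direct factorisation with one step
of iterative refinement. Touching cells are separated by a
marker-controlled watershed: markers are local maxima of the Gaussian-
smoothed (σ = 4 px) Euclidean distance transform, and each pixel joins
the marker of minimal topographic distance (total ascent along the best
4-connected path over the negative EDT), ties to the smaller marker
index — fully deterministic. Regions below 150 px are merged into their
dominant neighbour or dropped.

Because a projected spherical cell has no sharp rim — the optical chord
tapers to zero at the outline — the walker's boundary lands mid-halo and
overshoots bright cells. A final per-cell refinement trims each label to
pixels above 0.75 of the cell's own cytosolic plateau (floored at the
background noise level). The plateau is estimated over the cell's
organelle-free columns when the marker channel is available (marker
columns in the lowest 30% of the cell), because organelle columns are
several-fold brighter than cytosol and would inflate it; otherwise a low
percentile of the cell interior is used. All pixel-unit defaults were
calibrated on the synthetic fixtures; none is a measured constant.

**Quantification** (`spgfp.quantification`). Within each segmented
cell, the mitochondrial mask is `marker ≥ f · max(marker in cell)` with
f = 0.05; the per-cell record carries the median (configurably mean)
marker and reporter over the whole cell and the median reporter within
the mitochondrial mask. The fraction applies per cell by default (a
global-maximum scope is available). No background subtraction is
performed by default; an optional flag subtracts the median of the
unlabelled region first — necessary whenever the camera offset is
nonzero, since an additive offset otherwise drags the fractional
threshold below the background level. 3D mitochondrial pieces are
connected components (26-connectivity by default) of the same f-of-max
rule applied to the raw 3D marker within each cell; piece volume is
voxel count × dx·dy·dz.

**Kinetics** (`spgfp.kinetics`). Cells on an agar pad are effectively
stationary, so tracking is greedy maximum-IoU matching between
consecutive frames (matches below IoU 0.5 rejected; unmatched cells end
their trajectory, flagged incomplete). Fits need ≥ 4 points;
initialisation takes the plateau from the minimum value, the amplitude
from the first value and the rate from a log-linear regression on the
plateau-subtracted values, then bounded least squares (k ≥ 0). The
plateau term is included by default because the reporter does not decay
to zero (reconstituted GFP background persists); a pure exponential is
available by option. A fit whose modelled decline over the observation
window is below 5% of the initial level is flagged non-decaying, with
k = 0 and no half-life. Condition summaries are per-timepoint
mean ± SEM (SEM undefined at n = 1).

**Cytometry** (`spgfp.cytometry`). The gate τ is the linear-
interpolation empirical quantile (default q = 0.995, i.e. a 0.5%
false-positive allowance) of ≥ 100 negative-control events; positives
are events strictly above τ. Note the estimator's structural expectation
is `π·P(pos > τ) + (1 − π)(1 − q)` — for well-separated components,
about 0.37 percentage points above the true π at the defaults.

## Synthetic data generator

The generator (`spgfp.synthetic`) emulates the study conditions the
pipeline assumes; parameters stated by the experimental design are fixed
(0.5 µm z-step; 5-min frame interval; CCCP half-life 6.9 min, control
non-decaying; positive fraction 0.268), everything else is an emulation
choice documented here.

* **Geometry.** 20×256×256 voxels at 0.1×0.1×0.5 µm. Cells are
  spheroids with mild (±10%) per-axis eccentricity, radius 1.5–2.5 µm
  (yeast are 3–5 µm across), placed as a **monolayer**: centres jittered
  ±0.3 µm around the mid-plane and non-overlap enforced laterally with
  0.8 µm clearance. Cells on a pad do not stack along z; without this,
  cells would superimpose in the z-sum projection and no 2D segmentation
  could separate them. An explicit `touching_pair` flag places one pair
  at 0.92 × the touching distance (directional ellipsoid radii) to
  exercise watershed splitting.
* **Mitochondria.** Per cell, a persistent random-walk skeleton confined
  to the cell, dilated to a 0.25 µm tube radius; the tube surface keeps
  0.15 µm clearance below the membrane (cortical but inset, as in
  projections of real cells). Tube length is 0.75 µm per µm³ of cell
  volume — mitochondrial content scales with cell size (a constant
  volume fraction, ~15%), rather than a fixed length that would make
  small cells disproportionately dense.
* **Intensities.** Marker level 200 per mitochondrial voxel. Reporter
  `g_i ~ LogNormal(ln 300, 0.4)` on mitochondrial voxels plus a 5%
  cytosolic fraction over the cell (residual unassembled fluorescence);
  the scale is an exposure choice set so that the dimmest cells' outlines
  stay above the background noise floor, as an operator would choose
  acquisition settings. Background offset 10; isotropic Gaussian blur
  σ = 0.15 µm as PSF proxy; Poisson noise on (signal + background) then
  Gaussian read noise (σ = 2) — blur before noise, the standard camera
  model.
* **Ground truth** carries per-cell masks, mitochondrial voxel sets,
  skeletons (for independent re-rasterization), reporter levels `g_i`,
  decay rates, and `mito_median_ref`: the per-cell median reporter z-sum
  within the 5%-of-max marker mask computed on the noiseless, blurred,
  background-free rendering over the true cell masks. This is the
  estimand of the 2D quantification in its own operational definition
  and units; the raw level `g_i` is a per-voxel quantity that differs
  from the measured z-sum median by each cell's tube-crossing geometry,
  so recovery is validated against `mito_median_ref` (raw-`g`
  correlation is reported for context by `analysis/02`).
* **Time lapse.** Geometry is frozen across frames; the whole reporter
  signal scales by `2^(−t·Δt/t½)` before noise; the marker channel is
  constant; an optional scalar per-frame photobleaching factor applies
  to both channels. **Cytometry** draws component labels Bernoulli(π)
  and values from two log-normals (negatives ln 100 ± 0.4, positives
  ln 2000 ± 0.6 — well separated).
* **Determinism.** Each generator call consumes a single
  `numpy.random.Generator` seeded from one integer; identical parameters
  give bit-identical outputs.

What the generator does **not** emulate: depth-varying PSF, cell
motility or division, spectral bleed-through, autofluorescence
structure, scatter-based cytometry channels. Passing tests therefore
demonstrate correctness of the measurement machinery under the stated
model, not robustness to every real-microscope artefact.

## Numerical choices and degenerate inputs

* Walker: two classes; probabilities clipped to [0, 1]; a constant image
  falls back to uniform weights; fully seeded images return the seeds.
  The 1e-6 weight floor bounds the system's condition number (raw
  weights underflow at large β) so the solution agrees with a dense
  solve to better than 1e-8 on small grids.
* Watershed ties go to the smaller marker index; a mask without any EDT
  maximum falls back to its connected components; empty masks return
  empty label maps.
* An image with no foreground seeds yields an empty label map with a
  logged warning, not an exception.
* Quantification flags cells whose marker maximum is ≤ 0 (empty
  mitochondrial mask, NaN statistic) and keeps them in the output.
* Fits: non-convergence sets a flag rather than raising; time-lapse
  frames where a cell is missing propagate as missing values and fits
  use the available points.
* In the time-lapse workflow, segmentation runs on the **marker**
  channel: under CCCP the reporter decays ~400-fold over 13 frames and
  cannot support segmentation in late frames, which is exactly why the
  segmentation channel is configurable.

## Problem sizes

Defaults were chosen so every stage runs in seconds on one core: scenes
of 10 cells on a 20×256×256 grid, time lapses of 13 frames, cytometry
samples of 50,000 events; the segmentation-recovery validation uses 20
scenes. Larger fields and longer movies only change runtimes, not the
code paths.

## Known limitations

* 2D cell segmentation only (the quantification consumes projections);
  3D cell segmentation and mammalian-cell morphologies are out of scope.
* The outline IoU attainable against the true projected mask is bounded
  (~0.85–0.95) by the chord taper: the outermost rim of a projected
  spheroid contributes almost no photons at realistic exposure.
* The quantile gate over-counts positives by its false-positive
  allowance, `(1 − π)(1 − q)`; the analysis reports the raw gated
  fraction, as gates based on negative controls conventionally do.
* Tracking has no motion model and will fragment trajectories if cells
  move more than about half a diameter between frames.
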