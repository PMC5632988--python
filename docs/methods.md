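# Methods

## Overview

`dceseg` segments head-and-neck tumors in dynamic contrast-enhanced MRI by
classifying each voxel of a rough search region from the shape of its
time-intensity curve (TIC). The method has four parts: baseline
normalization of TICs, a 7-dimensional curve description (5 kinetic
parameters + 2 PCA projections), a cascade of three binary RBF-SVM
classifiers that successively strip vessels, cavity and normal tissue, and
overlap-based evaluation (AOM, CR, PM). Because no clinical dataset ships
with the package, a synthetic 4D phantom generator provides seeded,
ground-truthed data for training, testing and benchmarking.

## Curve model and features

The time axis is the 1-based dynamic-frame index `t = 1..65`. The physical
frame spacing (5.9 s by default) is carried as metadata only: every rate
feature is a ratio of differences on the same frame grid, so the time unit
cancels and carrying it through the formulas would only rescale two columns
of a table that is z-scored anyway.

Normalization divides by the mean of the first `n_pre = 8` frames (the
pre-injection baseline). Air- or fluid-filled voxels can have near-zero
baseline; the denominator is clamped to `clamp_eps × max(curve)` (default
`clamp_eps = 1e-6`) and the curve flagged invalid rather than producing
infinities. An all-zero curve normalizes to all zeros.

Kinetic features follow the standard semiquantitative definitions (peak
enhancement, time to peak, onset delay, mean wash-in and wash-out slopes).
Choices where the definitions are ambiguous on discrete, possibly flat
curves:

* `t_peak` is the **first** frame attaining the maximum (deterministic under
  ties, matches the "time to peak" reading).
* The wash-in slope is evaluated between the absolute frames `t_10%` and
  `t_peak`; the reported onset feature is the duration `t_10% − n_pre`.
  Evaluating a curve "at a duration" would be ill-posed.
* Degenerate denominators (`t_peak = t_10%`, peak at the final frame) give
  rate 0, not NaN: a flat segment legitimately has zero slope, and classifier
  inputs must stay finite.
* Non-enhancing curves (`i_max ≤ 0`) have no meaningful 10 %-of-peak
  threshold; `t_10%` is set to `t_peak` and wash-in to 0.

The PCA basis is fit once, on the normalized region-mean curves of the
training set, and frozen; test voxels are projected onto the stored
components. Curves are mean-centered before the eigendecomposition
(standard PCA), and each component's sign is fixed so its largest-magnitude
loading is positive — eigenvectors are otherwise sign-ambiguous and
downstream results would not be reproducible.

## Training table

One ROI per tissue class per sample; several ROIs of one class in a sample
are pooled as a union of voxels before averaging, preserving the
4-rows-per-sample structure. "Normalization across samples" is per-feature
z-scoring with the training table's own mean and SD; the statistics are
stored in the model and reused verbatim at test time (no peeking).
Constant columns (possible on degenerate synthetic tables) get SD replaced
by 1 with a warning.

## Cascade

Each stage is a binary RBF-SVM trained one-vs-rest on the **full** table
(not on progressively reduced tables): the sequential structure exists only
at test time, where stage 1 removes vessels, stage 2 cavity, stage 3 normal
tissue, and the residual is the tumor. The vessel and normal stages use the
5 kinetic features; the cavity stage uses the 2 PCA scores. The four output
masks partition the search ROI exactly, by construction.

Hyperparameters are grid-searched over the canonical powers-of-two ranges
`C ∈ 2^-5..2^15`, `γ ∈ 2^-15..2^3` (step 2²) with stratified 5-fold CV,
maximizing pooled CV accuracy; ties break toward the smallest `C`, then the
smallest `γ`, preferring the smoothest model and making training fully
deterministic for a fixed seed. Tables too small for 5 folds degrade to
leave-one-out, and folds whose training half contains a single class score
by majority prediction. The decision rule is the SVM's native sign (no
probability calibration). Classes are balanced by construction (one row per
class per sample), so no reweighting is applied.

## Evaluation

`AOM` is the Jaccard index; `PM = 100·TP/GT`; `CR = 100·(TP − 0.5·FP)/GT`
with `FP` the voxels predicted tumor outside the ground truth. CR is not
clamped: a segmentation drowning in false positives can legitimately score
below zero. Aggregation over the repeated protocol averages per-sample
scores within each repeat, then reports mean ± SD (ddof = 1) across the
repeat means.

## Phantom generator

Each sample is one 96 × 96 slice (a 144 × 144 × 20 grid is available via
config, but a single slice exercises every code path at desk scale) with 65
frames and injection after frame 8. Geometry per sample: an elliptical
tumor (radii 9–14 px), 2–4 circular vessels (radii 3–5 px), a rectangular
cavity (10–16 px sides), normal background; regions are disjoint by
rejection sampling and each occupies ≥ 20 voxels.

Class curve templates are piecewise linear on the normalized scale — zero
to the onset frame, linear rise to the peak, linear decay to the final
frame — the simplest shape that exercises all five kinetic features with
analytically known values (a gamma-variate shape is available as a
non-default switch). Default archetypes encode the qualitative orderings of
real tissue curves: vessel (onset 9, peak 12, peak enhancement 3.0, end
1.0), tumor (10, 20, 1.5, 1.2), normal (12, 40, 0.5, 0.45), cavity (peak
0.02 with baseline 5 % of the tissue baseline of 100). So vessel > tumor >
normal > cavity in amplitude and vessel < tumor < normal in peak time.

Randomness enters at three levels, all driven from one seed through
`SeedSequence` spawning:

* **frame noise** — additive white Gaussian, SD = 3 % of the class baseline
  per frame (typical of 3 T dynamic imaging);
* **per-voxel jitter** — curve amplitude scaled by a 5 %-SD factor and the
  peak frame shifted by an SD-1 integer jitter, emulating within-region
  heterogeneity;
* **between-sample variation** — each sample rescales every class's
  amplitude by a 20 %-SD factor (truncated to [0.6, 1.4]) and shifts
  onset/peak frames with SD 1.5, emulating between-patient variability.

The 20 % / 1.5-frame scale matters: it sets the within-class spread of the
training table. Much tighter variation makes the table unrealistically
clean, the CV grid search then cannot distinguish smooth from overfit
kernels (everything reaches CV accuracy 1.0) and occasionally selects a
narrow-γ model that generalizes poorly to noisy single-voxel curves. The
chosen scale is in the range of reported between-patient variability of
semiquantitative DCE parameters and keeps hyperparameter selection
meaningful.

The search ROI handed to the segmenter is the tumor bounding box padded by
4 px — a snug "roughly drawn" rectangle, as a radiologist would place it.
The padding controls how much non-tumor tissue the cascade must reject and
hence directly scales the false-positive opportunity.

### What the phantom does and does not emulate

It emulates: class-distinct enhancement kinetics, baseline differences
(near-zero-signal cavity), frame noise, within-region and between-sample
variability, and the train/test asymmetry of the method (training on clean
region means, testing on noisy single voxels). It does **not** emulate MR
physics (coil sensitivity, T1 saturation, k-space artifacts), partial-volume
boundary voxels, motion, mucosal tissue with tumor-like kinetics, or
irregular lesion shapes. Passing benchmarks therefore demonstrates the
mechanics and noise robustness of the pipeline on well-posed data, not
clinical-grade performance.

## Benchmark protocol and problem sizes

The default protocol matches the evaluation design: 10 repeats, each
simulating a fresh cohort of 80 training and 40 test samples, retraining
the cascade from scratch and scoring every test segmentation; repeat `r` of
a run with seed `s` draws all randomness from `SeedSequence([s, r])`. On one
CPU a full run takes on the order of a minute. At seed 1 the defaults give
mean AOM ≈ 0.81, CR ≈ 87 %, PM ≈ 98 %; other seeds land in roughly the
0.70–0.81 / 77–87 % bands, with per-repeat AOM spanning ~0.57–0.91. The
residual-tumor construction makes misses rare (high PM) and concentrates
errors in normal-tissue voxels whose noisy curves cross the 10 %-of-peak
threshold early or peak-shift far from the class mean, leaking through
stage 3 as false positives. The weak repeats are precisely those where the
grid search resolves a saturated CV score with a narrow-γ normal stage
(γ ≥ 2 instead of the typical 0.5); see Known limitations.

The examples use smaller cohorts (15–20 training samples) purely for
illustration speed; small training tables select hyperparameters less
stably and score a few points lower.

## Known limitations

* Tumor is the fall-through class: any voxel unlike *all* training classes
  ends up labeled tumor. This is faithful to the cascade design but means
  outlier curves inflate false positives rather than being rejected.
* Voxel-level `t_onset` and `t_peak` are noise-sensitive on flat or
  plateau-shaped curves; the training table, built from region means, does
  not exhibit this noise, so CV-selected hyperparameters cannot adapt to it.
* Grid-search CV accuracy saturates on small, well-separated tables, making
  the (C, γ) choice tie-break-driven; occasional narrow-γ selections cause
  visibly weaker repeats.
* No spatial regularization or morphology: every voxel is classified
  independently.
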