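# dceseg

Automatic tumor segmentation in dynamic contrast-enhanced MRI (DCE-MRI) of
the head and neck, built on time-intensity-curve (TIC) analysis and a
cascade of support vector machines — plus a seeded synthetic phantom
generator so the whole pipeline can be trained, tested and benchmarked
without access to clinical data.

**Who it is for:** researchers in quantitative DCE-MRI and medical image
analysis who want a tested, reproducible reference implementation of
TIC-feature-based voxel classification, or a controllable 4D phantom to
evaluate segmentation methods against known ground truth.

## Method

A DCE-MRI acquisition is a 4D array over `(x, y, z, t)`: T1-weighted frames
acquired repeatedly while a gadolinium bolus (injected around frame 8 of 65)
diffuses into tissue. Each voxel's TIC is first made dimensionless by its
own pre-injection baseline,

    i_real(t) = (i_n(t) − i_pre) / i_pre,       i_pre = mean of frames 1..8,

and summarized by **seven features**: five kinetic parameters

* `i_max = max_t i_real(t)` — peak enhancement,
* `t_peak` — first frame attaining the peak,
* `t_onset = t_10% − t_8` — frames from injection until 10 % of peak,
* `wash_in  = (i(t_peak) − i(t_10%)) / (t_peak − t_10%)`,
* `wash_out = (i(t_peak) − i(t_65)) / (t_65 − t_peak)`,

and the projections onto the first two principal components of the training
curves. Training supervision comes from one rectangular ROI per tissue class
(tumor, vessel, normal tissue, cavity) per sample; the region-mean TIC of
each ROI gives one 7-feature row, z-scored with the training statistics.

Segmentation runs three binary RBF-SVM classifiers (each trained
one-vs-rest, `C` and `γ` grid-searched by stratified 5-fold CV) in sequence
over every voxel of a rough search ROI: vessels are removed first (kinetic
features), then cavity (PCA features), then normal tissue (kinetic
features); the residual voxels are the tumor. Results are scored against
ground truth by the area overlap measure `AOM = |A_R ∩ A_G| / |A_R ∪ A_G|`,
percent match `PM = 100·TP/GT` and corresponding ratio
`CR = 100·(TP − 0.5·FP)/GT`.

## Worked example

`examples/02_train_and_segment.py` trains on 20 synthetic phantoms and
segments a held-out one:

```
training table: 80 rows x 7 features
stage 1 removes vessel  C=0.5      gamma=0.125      CV accuracy=1.000
stage 2 removes cavity  C=0.125    gamma=0.5        CV accuracy=1.000
stage 3 removes normal  C=0.125    gamma=0.5        CV accuracy=1.000

search ROI: 1015 voxels; removed per stage:
  vessel      0 voxels
  cavity      0 voxels
  normal    372 voxels
residual tumor mask: 643 voxels
vs ground truth (403 voxels): AOM=0.627  CR=70.2%  PM=100.0%
```

Every true tumor voxel was recovered (PM 100 %); the AOM of 0.63 on this
small-cohort example reflects normal-tissue voxels whose noisy curves leak
through the last stage into the residual — the characteristic error mode of
the cascade. (The full 80-sample protocol scores substantially higher; see
below.) The other examples show single-curve feature extraction
(`01_normalize_and_features.py`) and the repeated benchmark protocol
(`03_repeated_benchmark.py`).

A thin CLI mirrors the library: `dceseg simulate | train | segment |
evaluate | experiment` (see `dceseg --help`). Series are 4D NIfTI with time
as dimension 4; ROIs are JSON rectangles (0-based, half-open); masks are
uint8 NIfTI.

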