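# Methods

This document describes the quantification model, the preprocessing
pipeline, the synthetic scene generator and the numerical choices made in
`mnquant`. It is written for someone who wants to understand or audit what
the package computes, not just run it.

## Problem statement

Micronuclei (MN) and nuclear buds (NBUDs) are small chromatin bodies that
appear near or attached to a cell nucleus and are an established readout of
chromosomal instability (CIN). Given a nuclear-stain microscopy image and
an instance segmentation mask of the nuclei, the package:

1. cuts out one homogenized image patch per nucleus,
2. predicts the number of MN/NBUDs associated with that nucleus
   (a per-nucleus *CIN count*, an integer, in practice 0–3), and
3. aggregates counts into a per-image *CIN score*:

```
CIN score = (total MN + NBUD count) / (number of nuclei)
```

The package does not segment nuclei itself; it consumes any instance mask
(e.g. from a nuclear segmentation tool) and is robust to the mask not
containing the micronuclei themselves — MN are picked up from the pixels
around each nucleus, not from the mask.

## Patch extraction ("nuclei isolation")

For every labeled object in the mask:

1. **Tight bounding box** around the object's pixels (half-open pixel
   coordinates; `scipy.ndimage.find_objects`).
2. **Expansion** by 20 px on every side, clipped at the image border, so
   that detached MN near the nucleus are included.
3. **Area filter**: boxes whose tight area falls strictly below the 5th
   percentile of all tight-box areas in the image are dropped as
   segmentation debris. The percentile uses NumPy's default linear
   interpolation. With all-equal areas this is a no-op.
4. **Resampling**: the crop is rescaled by `ratio * final_size / max(w, h)`
   where `w, h` are the *tight*-box sides, `ratio = 0.65` and
   `final_size = 256`. This is the reciprocal of the reported scaling
   factor `ratio * max(w, h) / final_size`; after resampling the nucleus
   occupies 0.65 of the patch side (166 px of 256) regardless of its
   original size. Bilinear interpolation with anti-aliasing when
   downscaling; the mask can be projected through the identical transform
   with nearest-neighbour interpolation (`project_mask_patch`) for
   footprint measurements and saliency localization.
5. **Centering and padding**: the tight-box center lands on the patch
   center; out-of-crop pixels are filled with the crop minimum (a local
   background estimate, so border nuclei do not acquire artificial dark
   or bright frames).
6. **Brightness normalization**: per-patch min–max to [0, 1]; a constant
   patch maps to all zeros.

Quality control, reported per image and never silently applied:

- **Focus**: variance of the Laplacian of each patch; patches scoring
  below `blur_threshold` (default `1e-4`) count toward
  `pct_out_of_focus`. On the synthetic scenes sharp patches score
  ≥ 2.3e-4 and heavily blurred ones (Gaussian σ = 3) ≤ 5.3e-5, so the
  default sits between the two clusters.
- **Overlap audit**: pairwise IoU of the *expanded* boxes; pairs with
  IoU ≥ 0.5 are flagged, because two nuclei that share most of their
  patch can double-count each other's MN.

## Counting model

### Architecture

A small convolutional regressor (`small_cnn`) sized for CPU training:

- 2×2 average-pool stem (halves the resolution cheaply before any
  convolution),
- 3×3 same-padded conv + batch-norm + ReLU blocks with channel widths
  `conv_channels` (default (24, 48, 64, 64)), 2×2 max pooling after each
  of the first `n_pools` blocks,
- global average pooling, dropout (0.2), and a single-output linear head.

Batch normalization is what makes the short training budget work: without
it the validation loss is still falling when the desk-scale benchmark's
30-epoch cap is reached. Running statistics (momentum 0.1) are used at
inference and stored with the weights.

The model is a *regressor* trained with mean squared error on the integer
counts; predictions are rounded half-away-from-zero and clamped at 0 (no
upper clamp — counts above 3 are reported with a warning as
extrapolation). Regression plus rounding preserves the ordinal structure
of counts and penalizes a 0-vs-3 confusion more than a 2-vs-3 confusion,
which a cross-entropy classifier would not.

An EfficientNet-family backbone is part of the interface
(`ModelSpec.backbone`) but deliberately not implemented: it requires a GPU
deep-learning framework, and this package targets CPU-only environments.
Requesting it raises `NotImplementedError`.

The implementation is a self-contained NumPy framework (`mnquant.nn`):
im2col convolution over BLAS matmul, batch normalization (including the
backward pass through the batch statistics), analytic backward passes
validated against central finite differences in the test suite, inverted
dropout, Adam with bias correction, and a reduce-on-plateau scheduler.
Everything is float32 and fully deterministic given a seed.

### Training recipe

- Loss: MSE. Optimizer: Adam, initial learning rate 1e-3.
- Scheduler: reduce-on-plateau, factor 0.2, patience 10 (strict
  improvement, no minimum delta).
- Early stopping patience 30; at most 300 epochs; the weights with the
  best validation loss are kept.
- Global-norm gradient clipping at 2.0. At this dataset scale the
  validation loss occasionally spikes mid-training without it; clipping
  removes the spikes and markedly reduces run-to-run variance.
- After restoring the best weights, the batch-norm running statistics are
  recomputed over the unaugmented training set (the exponential estimates
  accumulated during training lag the restored weights and carry
  augmentation noise).
- Batch size 64, dropout 0.2.
- Augmentation (training batches only): random vertical/horizontal flips,
  rotation uniform in ±30° (bilinear, zero fill), and a 3×3 Gaussian blur
  applied with probability 0.3.
- Patch intensities are mapped from [0, 1] to [−1, 1] at the model input.
- The regression head's bias is initialized at the mean training label so
  early epochs are spent learning features rather than the output offset.

### Dataset balancing

Counts in realistic material are dominated by zeros. Before training:

1. drop patches with counts ≥ 4 (rare outliers), then
2. randomly downsample the zero-count patches to the total number of
   non-zero patches, so exactly 50 % of the balanced set has count 0
   (whenever zeros were in excess; otherwise all zeros are kept and a
   warning is emitted).

Splits are stratified by count (90/10 train/validation by default;
stratified k-fold is available). With fewer than 2 members in a class the
split falls back to unstratified with a warning.

### Saliency

`saliency_map` produces a class-activation map: the ReLU of the
head-weighted sum of the final feature maps, bilinearly upsampled to patch
size and normalized by its maximum. On trained models the map concentrates
on the micronuclei (verified statistically in the test suite).

## CIN scoring

- Per image: `cin_score = total count / number of nuclei` over the kept
  patches. `CinScoreReport` refuses inconsistent triples.
- Replicate aggregation reports both the mean of per-image scores
  (primary, every image weighted equally) and the pooled score
  (total counts / total nuclei), since they differ when image sizes differ.
- `monte_carlo_estimate` estimates a specimen-level score from random
  fields of view: FOV origins are drawn uniformly, nuclei are assigned by
  centroid, per-FOV ratios are averaged; FOVs with fewer than
  `min_nuclei_per_fov` nuclei are redrawn, and persistent failure raises
  an error naming the nucleus density.
- `compare_scores` reports RMSE, Pearson r, r², and the identity-line
  coefficient of determination (R² of prediction = truth, which penalizes
  bias, unlike r²); constant inputs set a `degenerate` flag rather than
  returning silent NaNs.

## Synthetic scene generator

The generator produces the ground-truth scenes used for training and
validation. Scope: it mimics the *geometry and photometry* of nuclear
stains well enough to train a counting model, not the biology of any
particular cell line.

- Nuclei are slightly elliptical disks placed by dart throwing with a
  minimum center separation of 2.8× the maximum nucleus radius; failure
  to place after many tries raises `PlacementError` (density too high).
- Per-nucleus CIN counts are drawn from `mn_count_distribution` (default
  (0.6, 0.3, 0.08, 0.02) over counts 0–3; `distribution_for_rate(ρ)`
  builds a distribution with expected rate ρ for rate-sweep experiments).
- MN radii are 0.16–0.30 of the parent radius with a 1.6 px floor
  (smaller objects do not survive the global blur). Detached MN centers
  lie in an annulus 1.05–1.35× the parent radius, which keeps them inside
  the patch at the 0.65 nucleus-to-patch ratio; attached NBUDs overlap
  the nucleus boundary by at most 2 px. If a detached position cannot be
  found in a crowded neighbourhood, the MN is rendered attached instead
  (recorded in `mn_records`).
- MN intensity is the parent intensity ±20 %.
- Decoy phenotypes with true count 0: apoptotic nuclei (5–12 scattered
  fragments) and mitotic figures (two bright lobes).
- The whole scene gets Gaussian blur (σ = 1) and additive Gaussian noise;
  the mask contains *only* the nuclei (MN are never in the mask), exactly
  like the output of a nuclear segmentation tool.
- `truth` records per-nucleus counts; `mn_records` records every rendered
  MN with position, radius and attachment, enabling localization tests.

## Desk-scale benchmark

`mnquant.benchmarks.run_benchmark(seed)` is the package's standard
self-evaluation (also used by `scripts/acceptance.py`):

- 26 training scenes of 100 nuclei at 576×576 px → ~2,500 labeled patches
  extracted at a 96 px working resolution,
- balance, stratified 20 % hold-out, inner 90/10 validation split,
- train ≤ 30 epochs with the full recipe,
- hold-out weighted F1 and multiclass MCC on rounded counts,
- 12 evaluation scenes with expected CIN rates on a grid in [0, 0.5]
  (via `distribution_for_rate`), scored end-to-end; Pearson correlation
  of predicted vs ground-truth per-scene CIN scores.

All randomness derives from the single benchmark seed through named
SHA-256 sub-seeds, so runs are exactly reproducible.

## Numerical choices and conventions

- Rounding of raw counts is half-away-from-zero (0.5 → 1, 1.5 → 2), then
  clamped at 0. Bankers' rounding would map 0.5 → 0 and 1.5 → 2,
  biasing adjacent classes differently.
- Percentiles use linear interpolation (NumPy default); the area filter
  removes strictly-below-cutoff boxes.
- All seeded randomness uses `numpy.random.default_rng`; derived seeds
  are taken modulo 2³¹.
- Images are float32 in [0, 1] internally; 8/16-bit integer TIFFs are
  scaled by their dtype maximum on read.
- Bounding boxes are half-open `[y_min, y_max) × [x_min, x_max)` in
  (row, column) order.

## Limitations

- The counting model is trained and validated on synthetic scenes; on
  real microscopy data it should be retrained or fine-tuned on labeled
  patches from the same staining protocol.
- The generator renders near-circular nuclei without texture; highly
  lobulated or textured nuclei are out of scope.
- Attached NBUDs with small protrusions are intrinsically the hardest
  class; most residual counting error concentrates there.
- The per-nucleus count saturates at 3 in the training distribution;
  higher counts are extrapolation and flagged by a warning.
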