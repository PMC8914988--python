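# Methods

This note documents the models, conventions and numerical choices behind
`smartsleeve`, in the order data flows through the pipeline.

## The measurement model

The instrument is a 20×10 matrix of resistive textile pressure sensors
worn on the forearm, read by 12-bit ADCs (integer counts in [0, 4095]) at
50 Hz. The unit of analysis is not the raw 50 Hz stream but the
*average image* of one activity execution: most target activities are
static postures, so the per-activity mean over a recording is a stable
summary. One dataset row is therefore a (subject, round, activity)
triple with one 20×10 averaged image; a *round* is one wearing session,
and the sleeve is taken off and re-worn between rounds.

## Synthetic-data generator

The generator emulates the statistical structure of such a dataset so
that every downstream stage is testable without recordings.

* **Activity archetypes.** Each of the 18 activities is a sum of one to
  two anisotropic Gaussian bumps `(center_row, center_col, row_sd,
  col_sd, amplitude)` on the grid (`activities.yaml`). Values below
  `blob_floor` (default 150 counts) are truncated to zero: a contact
  print has compact support — the fabric reads zero where nothing
  presses — whereas an untruncated Gaussian with amplitude in the
  thousands stays above the 2-count activity threshold across most of
  the grid and would saturate any area measure. Spreads are sized so
  patches do not clip at the grid border; clipped patches lose exactly
  the content that rescaling would need to restore.
* **Body-size effect.** Subject anthropometrics are sampled uniformly
  over plausible adult ranges (forearm length 23–28 cm, biceps
  circumference 21–38 cm). A subject's blob geometry is stretched by
  `L_FA(i)/mean(L_FA)` along rows and `L_BC(i)/mean(L_BC)` along
  columns, about the grid origin. This makes the anthropometric rescale
  (below) the exact inverse of the injected effect, which is what the
  recovery tests exercise. `size_effect` in [0, 1] interpolates the
  strength (0 disables it, e.g. for ablation controls).
* **Re-wearing offsets.** One rigid shift per (subject, round), drawn
  from a Gaussian with `round_offset_sd = 1` grid pixel and rounded to
  integers — a sleeve settles a centimeter or so differently each time
  it is put on.
* **Noise.** Additive Gaussian noise with `noise_sd = 1` ADC count,
  then integer quantization and clipping to [0, 4095]. The small default
  is deliberate: the sample is an *average* of hundreds of raw frames,
  so tens of counts of per-readout noise shrink to ~1 count in the mean.
  Raw-frame noise levels can be emulated by raising `noise_sd`.

What the generator does **not** model: biomechanical realism of the
patch shapes, the 50 Hz temporal stream, sensor drift and hysteresis,
between-round posture variation beyond a rigid shift, and activity
archetypes that overlap as heavily as some real activities do (writing
variants, armrest postures). Passing tests therefore demonstrate that
the pipeline's machinery is correct and that it removes exactly the
nuisance effects the generator injects — not that real-data accuracy
will reach any particular level; synthetic accuracies sit near the
ceiling because the archetypes are more separable than real postures.

## Preprocessing

Shape chain per frame: 20×10 → (×3 bilinear upsample) 60×30 → (5×5
Gaussian, σ = 1, reflective borders) → (anthropometric rescale) →
(center onto 84×42, rigid per-round shift) 84×42.

* **Interpolation convention.** All resampling is corner-aligned
  bilinear: output sample positions are `linspace(0, H−1, out_h)` per
  axis, so first/last samples coincide with the input borders and
  constants are reproduced exactly. A σ = 1, 5-tap Gaussian is the
  conventional pairing for a 5×5 kernel; reflective borders preserve
  constants and avoid darkened edges on these small images.
* **Rescale mapping.** Rows (along the arm) are tied to forearm length,
  columns (around the arm) to biceps circumference:
  `alpha = mean(L_FA)/L_FA(i)`, `beta = mean(L_BC)/L_BC(i)`; the output
  size is `round(H·alpha) × round(W·beta)`. Ratios of exactly 1
  short-circuit to the identity.
* **Alignment.** The scaled image is embedded centered on an 84×42 zero
  canvas (the final size leaves headroom so shifting discards little
  content). Exposure images are computed per round from these embedded
  images, so centers of mass are comparable across rounds of different
  scaled sizes. Offsets are `target − com(round)` with the target the
  mean of all round centers; offsets therefore average to zero.
  Fractional offsets are applied by bilinear resampling rather than
  rounding, since centers of mass are fractional; the result is clipped
  at zero to guard interpolation round-off. A fully empty dataset (no
  round has a defined center of mass) aligns with zero offsets.
* Both the smoothed and the normalized image are kept per sample:
  rescaling and shifting can destroy information, so downstream stages
  see the original too.

## Feature set

100 features per image, exactly, on every input; 200 per sample.
Coordinates: origin at the upper-left pixel center, x along the short
side (columns), y along the long side (rows); angles in radians from the
positive x-axis.

Conventions that keep every feature finite and well defined:

* **Activity threshold.** Wherever "area" means a pixel count
  (centroid support, bounding rectangle, `Feat21`, symmetry side areas),
  a pixel participates iff its value is ≥ 2 ADC counts. The threshold
  is kept on the raw ADC scale after smoothing and rescaling, since
  bilinear operations preserve the value range.
* **Coverage** is the fraction of strictly positive pixels (a
  non-negativity-based definition would be vacuous on clipped data).
  Quantile coverages sort pixels descending and count the smallest
  prefix reaching 25/50/75 % of total pressure. Region coverages split
  the grid at ⌊H/3⌋ rows and ⌊W/2⌋ columns (top-left, top-right,
  bottom-left, bottom-right).
* **Contours** are 8-connected regions of the image binarized strictly
  above its mean pixel value; per-region area, pressure and intensity
  (pressure/area) feed the maxima `Feat38–40`. The *masked image* keeps
  only the region with maximal pressure, ties broken toward the first
  region in row-major scan order.
* **Hu moments** are computed on the intensity-weighted image via
  normalized central moments; an all-zero image reports seven zeros.
* **Degenerate inputs.** Empty support: centroid and center of mass
  fall back to the image center, distances/angles are computed from it,
  bounding boxes report zeros. Ratios: `0/0 → 1` (two empty sides are
  balanced), `x/0 → 10⁶` (capped, never infinite). Entropy of an
  all-zero image is 0. These rules guarantee a finite 100-vector for
  any non-negative image.
* **Symmetry splits** assign a pixel to the left/upper side iff its
  coordinate is strictly below the split value, so the two sides
  partition the image and side pressures sum exactly to the total.
* **Contact area** (`features.contact_area`) — used by diagnostics and
  the recovery analyses rather than the per-image feature vector — is
  peak-relative: pixels ≥ 10 % of the image's maximum. Upsampling and
  smoothing surround every patch with a low-amplitude skirt whose width
  is fixed in pixels by the processing, not by the subject; a near-zero
  absolute threshold mostly measures that skirt and hides the size
  effect the normalization removes.

## Evaluation

* Min–max normalization is fitted on the training split only and
  applied to the test split with clipping to [0, 1]; constant training
  columns map to 0. Fitting per training fold avoids test-set leakage;
  the alternative (fitting globally) changes little here but is the
  less defensible protocol.
* 10-fold CV is stratified with a seeded shuffle (classes are balanced
  by design, one instance per activity per round, so stratification is
  the natural reading); LOSO holds out each subject once.
* Per-fold metrics are averaged across folds; the confusion matrix
  pools all test predictions. The macro-F1 of a result is recomputed
  from the averaged macro-precision/recall so the harmonic-mean
  identity holds exactly on every emitted result. Per-class precision
  or recall with an empty denominator counts as 0.
* Classifier hyperparameters: SVM polynomial kernel; KNN 5 neighbors;
  logistic regression l2, ≤ 8000 iterations; random forest balanced
  class weights, Gini, log2 features; decision tree; Gaussian naive
  Bayes; seeded estimators use a fixed random state of 40, everything
  else keeps scikit-learn defaults.
* **Ablation.** "Without normalization" drops the normalized image and
  its 100 features, leaving classifiers the smoothed image's features
  only. "Without the new feature set" restricts each image to a
  38-feature baseline subset (statistical block + basic geometric
  descriptors, `evaluation.BASELINE_38`) — a documented stand-in, since
  the external 38-feature spatial set it emulates is not enumerated
  alongside the 100-feature set.

## CNN

Three blocks of (3×3 conv, stride 1, pad 1) → batch normalization →
ReLU → (2×2 max pool, stride 2), channels 64/128/256, pool spatial
paddings (0,1), (1,1), none, giving the spatial trace 20×10 → 10×6 →
6×4 → 3×2 (validated at construction); flatten (1536) → dense → 18
scores. Inputs are raw frames divided by 4095 — standard scaling for
bounded sensor data. Loss is softmax cross-entropy; the optimizer is
Adam at lr 10⁻⁴, 30 epochs, batch 40, He-initialized from a seeded
generator, full re-initialization per cross-validation fold.

Implementation notes: the network is written directly on NumPy in
float32 — im2col patch extraction with matrix products for the
convolutions, nine-offset scatter-adds for their backward pass, batch
statistics with running means (momentum 0.9, ε 10⁻⁵) for batch norm.
Max-pool padding uses −∞ semantics so padded cells never win the max
(equivalent to zero padding on the non-negative post-ReLU activations,
but correct by construction). At 20×10 inputs this trains at roughly a
second per epoch per ~300 samples on one CPU core.

## Problem sizes

The test suite and the acceptance script run the classifier studies at
6 subjects × 3 rounds × 18 activities (324 samples) and the structural
checks at the full 14 × 10 × 18 (2520 samples); the CNN cross-validation
uses 5-fold and per-subject folds at the reduced scale. These sizes keep
the full pipeline — generation, preprocessing, 200-feature extraction,
six classifiers under two schemes, and per-fold CNN retraining —
comfortably reproducible on a single CPU while leaving every effect the
generator injects statistically visible.

## Known limitations

* The synthetic archetypes are more separable than real postures;
  absolute synthetic accuracies are ceilings, not forecasts.
* The 38-feature ablation baseline approximates, but is not, the
  external spatial feature library it stands in for.
* Rescaling about the grid origin matches the generator's size model;
  for real data a subject's patch may scale about an anatomical anchor
  instead, which a rigid shift only partly absorbs.
* The exposure-image alignment assumes one rigid offset per round;
  rotations or nonuniform slippage are not modeled or corrected.
* The CNN is CPU-oriented; it makes no attempt at GPU-scale training,
  augmentation, early stopping or architecture search.
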