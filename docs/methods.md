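# Methods

`leukofrac` implements a weakly-supervised differential leukocyte counter
for label-free multiphoton microscopy: given a stitched two-channel mosaic
(third-harmonic generation, THG; two-photon excited autofluorescence,
2PEF) of a blood fraction or bronchoalveolar lavage fluid (BALF) sample, a
fully-convolutional network regresses the fractions of neutrophils,
eosinophils, lymphocytes and macrophages/monocytes directly from the
image, supervised only by image-level differential counts. Because no
public image data exist for this modality, the package includes a
synthetic mosaic generator that reproduces the documented morphology of
the four classes, and a morphometry oracle that closes the loop by
re-measuring what the generator drew.

## Synthetic mosaic generator

Each mosaic is a field of non-overlapping cells on a dark background at a
configurable density (cells/mm^2) and class composition. Defaults encode
the reported morphology of the four classes:

| class       | diameter (um)  | nucleus            | THG     | 2PEF    |
|-------------|----------------|--------------------|---------|---------|
| neutrophil  | 8.9 +- 0.7     | 2-5 lobes          | high    | low     |
| eosinophil  | 8.7 +- 0.6     | 2-3 lobes          | high    | high    |
| lymphocyte  | 7.1 +- 0.8     | mononuclear        | low     | low     |
| macrophage  | 19.6 +- 3.0    | mononuclear        | varying | varying |

Reference cell densities per sample type: granulocyte fractions 4808,
PBMC fractions 6464, BALF 549 cells/mm^2. Reference compositions for the
thirteen clinical samples (4 granulocyte, 3 PBMC, 6 BALF) ship as
defaults for dataset generation.

Design choices where only qualitative information exists:

- **Diameters** are truncated normal (+-3 SD, floored at 0): the simplest
  distribution matching the reported mean +- SD.
- **Intensity levels**: high = 0.7 and low = 0.2 of the dynamic range,
  varying = uniform(0.2, 0.7), with +-10% per-cell jitter and additive
  Gaussian sensor noise (SD 0.03). Only the *ordinal* contrasts are
  documented (granulocytes >> lymphocytes in THG; eosinophil >>
  neutrophil in 2PEF), and only those are asserted by tests.
- **Nuclei** render as attenuated (x0.35) ellipses: granulocytes get
  `n_lobes` jittered overlapping lobes with axes 0.30-0.45 x diameter,
  mononuclear classes one kidney-offset ellipse.
- **Macrophages** get a boundary perturbed by low-order Fourier modes
  (renormalized so the enclosed area still matches the sampled
  equivalent diameter) and a speckle texture standing in for
  pigment/vesicle content; no quantitative description of either exists.
- **Placement** is uniform rejection sampling with centres at least
  (d_i + d_j)/2 apart (a spatial hash keeps this O(n)); an optional
  clumping flag relaxes the distance to 60% to emulate touching cells.
  An unachievable density raises an error naming the density actually
  reached. Cell class is drawn independently per cell, so realized
  fractions fluctuate multinomially around the request; the exact
  realized fractions are stored as ground truth.
- **Artifacts** (all optional): a smooth glass-interface plane in THG
  (0.15 +- 0.03 — interface THG is strong, well above the noise floor),
  a multiplicative per-tile vignette dropping to 0.65 at stitching-tile
  corners, and irregular "dirt" objects with their own mask channel.
- Coordinates: top-left origin, x rightward, y downward; physical units
  micrometres throughout; 0.5 um/px default pixel size.

What the generator does **not** emulate: activated-cell morphology
(enlarged lymphocytes, multinuclear giant cells), basophils/plasma
cells, 3D depth structure, focus drift, and the full texture statistics
of real cytoplasm. Passing tests therefore demonstrate that the
*pipeline* recovers what it is pointed at under the documented contrasts
— not clinical performance on patient images.

## Preprocessing

`gamma_correct` (factor 0.7, the acquisition-software convention; off by
default for synthetic data, which is linear) -> `subtract_background`
(rolling ball) -> `apply_clahe` -> `normalize_pixel_size` (0.5 um/px,
down-scaling only) -> `split_mosaic` (> 2500 px sides quartered, each
quadrant inheriting the label). Numerical choices:

- Rolling-ball radius defaults to 25 um (largest macrophage + margin;
  the background must be smooth at cell scale). The ball runs on a 4x
  down-sampled, lightly smoothed copy (the ImageJ "shrink" device —
  equivalent for backgrounds varying over tens of micrometres, ~100x
  faster), with intensities scaled to the 0-255 convention so the ball
  is steep enough not to roll into cell-sized peaks, and a median DC
  correction because a morphological opening tracks the *lower envelope*
  of the noise rather than its centre.
- CLAHE clip limit 0.01, tile 64 px: mild equalization; constant
  channels pass through unchanged.
- Down-scaling uses exact local-mean binning for integer factors,
  anti-aliased resampling otherwise.
- Background subtraction precedes CLAHE (the order is not documented;
  equalizing first would amplify the glass plane before removal).

## Morphometry oracle

An independent measurement path used to validate the generator (the
counterpart of measuring 100 cells per class by hand): max-projection
over channels, Gaussian smoothing (sigma 1 px), a global threshold chosen
as the lowest of {2-class Otsu, 3- and 4-class multi-Otsu levels} that
clears the background-noise floor (median + 8 MAD) — a plain Otsu puts
its threshold above the dim lymphocyte population when bright
granulocytes are present — hole filling, watershed on the smoothed
distance transform to separate tangent cells, and per-component
re-thresholding at the half-rise point (background + 0.45 x (plateau -
background), plateau = 75th percentile of the eroded core). The
half-rise refinement removes the mask inflation a single low global
threshold causes; on calibration ensembles the diameter bias is under
0.15 um for every class, and detection precision/recall on
non-overlapping fields exceeds 0.99. Size gates default to 4-40 um.

## Model

A fully-convolutional trunk, global average pooling, a 4-unit dense
layer and softmax; the simplex output encodes that differential counts
sum to 1, and global pooling admits any input size above 64 px at fixed
pixel size. The desk-scale backbone ("simple_cnn", the default) is a
parameter-free 2x2 mean-pool stem followed by five 3x3 convolution
blocks of widths (16, 32, 64, 128, 128) — strides (2, 2, 2, 2, 1), so
the final feature map resolves individual cells (one unit per ~32 px at
0.5 um/px) — implemented directly on numpy arrays with hand-written
forward/backward passes: deterministic, dependency-light, and fast
enough for CPU training (~240k weights). The stem halves the working
resolution so the conv hierarchy sees whole cells early (lymphocytes fit
the second block's receptive field, macrophages the fourth).

Several stabilizers matter at batch size 1 with an MAE loss (whose exact
gradients have constant magnitude):

- **bias-free convolutions** — under scale-normalized (Adam) updates a
  conv bias otherwise outgrows the input-dependent response and the
  network collapses to predicting the label median;
- **per-channel instance normalization** (trainable gain, no shift)
  after every conv except the last block — the pooled features must keep
  magnitudes that scale with the density of the evidence. The norm uses
  a variance floor (3e-3): without it, channels nearly silent on an
  image have their background noise amplified to unit variance, making
  empty background as salient as cells;
- **leaky ReLU** (slope 0.1) so no unit can die permanently;
- **reflect padding**, so constant inputs produce constant feature maps
  (this also makes the output of homogeneous content size-invariant).

The large generic-image backbones (ResNet50, EfficientNetV2B0,
MobileNetV2) are recognized configuration names but require a GPU
deep-learning backend and pretrained weights; selecting them raises a
clear error. Checkpoints (.npz) embed the config, seed and class order.

## Training

Class-weighted mean absolute error between softmax output and reference
fractions: `(1/4) sum_c w_c |y_c - p_c|`, with inverse-frequency weights
`w_c = 1/(mean_c + 0.01)` normalized to mean 1 (the weight formula is a
package choice; only the use of class weights is documented). Adam, a
one-cycle schedule (cosine ramp to a peak over the first 30% of epochs,
annealing to initial/10), the trunk frozen for the first epoch (head
warm-up), gradients accumulated over a few mosaics per step (mosaics
vary in size, so true batching is impossible), early stopping on the
*raw* validation MAE (min-delta 1e-4), best-validation weights restored.
Two numerical choices matter for from-scratch optimization:

- the backward pass uses a pseudo-Huber smoothing (delta 0.02) of the
  |.| subgradient — the exact sign gradient has constant magnitude, so
  near the conditional median per-sample signs cancel and weak class
  signals (rare eosinophils) cannot accumulate; the reported losses are
  still plain (weighted) MAE;
- the head bias is initialized at the log of the training-label prior:
  softmax logit gradients scale with the predicted probability, so a
  class whose output starts far below its prior recovers only
  exponentially slowly.

Augmentation per presentation: 90-degree rotations, flips, per-channel
brightness/contrast jitter; saturation/hue jitter only in RGB-composite
mode; free-angle rotation available but off by default. The default
jitter is +-20%; the desk schedule uses +-10% because in two-channel
mode the absolute channel intensities are class evidence (2PEF level
separates eosinophils from neutrophils) and stronger jitter erases it.
The reference protocol values (initial LR 1e-5, 200 epochs, one-cycle
peak 10x, patience 15, accumulate 4) are the `TrainConfig` defaults and
presume a pretrained trunk; `TrainConfig.desk()` is the from-scratch CPU
schedule used by the synthetic experiment (initial LR 2e-4, peak 5x, 30
epochs, accumulate 2, patience 15).

## Evaluation

Predictions are grouped by case; a case report carries the mean +- SD
(sample convention, ddof = 1) over its mosaics against the reference
fractions. The set MAE is reported both as the mean over cases and the
mean over mosaics (they coincide when all cases contribute equally).
Accuracy is defined as `100 x (1 - set MAE by case)` — "accuracy" has no
standard definition for fraction regression; this one makes a set MAE of
0.087 read as 91.3% — with a stricter max-class-error variant available.

## Grad-CAM audit

Maps use gradients of the *pre-softmax* class score at the last conv
block (standard practice; post-softmax gradients couple the classes),
rectified weighted feature sums, bilinear upsampling and per-map min-max
normalization (constant maps normalize to zero). With global pooling
directly after the last block the channel weights reduce to the head
weights — the maps are exact, not sampled. Overlays use a
blue-green-yellow-red ramp with an embedded colorbar. The quantitative
audit compares mean activation over the generator's cell masks against
the background; a trustworthy counter scores ratio > 1 for every class.

## Desk-scale experiment and problem sizes

The end-to-end synthetic experiment trains on 31 BALF-type cases (21
train / 5 validation / 5 test) of three 512 x 512 px mosaics each at the
BALF density (~36 cells per mosaic), with case compositions stratified:
within each split, cases cycle through the six clinical BALF reference
rows before Dirichlet jitter, so every split covers compositions from
macrophage-dominated to neutrophil-dominated lavages (with only a
handful of cases per split, purely random archetype choice can leave a
split without, say, any eosinophil-rich case — a tiny-n sampling
artifact, not a property of the method). More, smaller cases beat fewer,
larger ones here because composition coverage is what limits accuracy.
Training items are 16 overlapping 256 px crops of each training mosaic,
inheriting the mosaic label — an extension of the reference protocol's
device of treating mosaic quadrants as individual cases, used to
multiply the number of optimization steps per epoch; validation and test
predictions always use full mosaics. Labels are the generator's realized
fractions (exact ground truth). These sizes keep the full experiment
within minutes on one CPU while leaving ~110 cells per test case, enough
for case-level fraction errors of a few percentage points to be
resolvable.

## Known limitations

- Synthetic appearance is far cleaner than clinical BALF (no mucus, no
  debris beyond the dirt model, no activated-cell morphology); accuracy
  numbers on synthetic data do not transfer to patients.
- The GAP -> linear -> softmax head must approximate a count-ratio (a
  ratio of pooled quantities) with a linear readout; extreme
  compositions are compressed toward the training prior. The dominant
  residual error of the desk model is under-counting of lymphocytes in
  lymphocyte-rich cases, followed by under-estimation of eosinophils —
  the latter matching what was observed clinically for this kind of
  weakly-supervised counter. Mean case-level accuracy is robust (93-97%
  across dataset seeds), but the *maximum* per-class case error varies
  roughly between 7 and 25 percentage points with the dataset seed.
- The Grad-CAM audit (cell vs background activation) passes reliably for
  the eosinophil and macrophage maps but not always for the neutrophil
  (and occasionally lymphocyte) map. At a fixed plating density the
  empty-background area anti-correlates with macrophage content
  (macrophages cover ~6x the area of the other classes), so background
  is a genuinely predictive cue for the small-cell fractions — the same
  mechanism reported for models trained on unprocessed clinical mosaics.
  Background subtraction removes the glass signal but cannot remove the
  area cue.
- The morphometry oracle assumes non-overlapping cells; clumped fields
  (clumping flag) are outside its validated envelope.
- Bit-for-bit training reproducibility holds for a fixed seed on a fixed
  BLAS; across BLAS builds only statistical reproducibility is claimed.
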