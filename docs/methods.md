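# Methods

## Problem

Abdominal adipose tissue splits into a subcutaneous compartment (SAT, the
fat ring between skin and the muscular wall) and a visceral compartment
(VAT, fat inside the abdominal cavity). Both are measured from axial
T1-weighted (in-phase) MR series by segmenting each slice into
{background, SAT, VAT} and integrating class areas across slices.
`fatseg` implements the full pipeline — segmentation networks, a
histogram-threshold baseline, volumetry, and agreement statistics —
together with a synthetic phantom generator that provides exact ground
truth, so every stage can be trained and validated without patient data.

## Synthetic phantoms

Each phantom subject is an axial series built from analytic geometry in
physical units (mm), rasterised on the acquisition grid:

* **Acquisition** (defaults): 50 slices, 10 mm thickness, 0.5 mm
  interslice gap, 530 mm field of view on a 480 x 480 matrix
  (1.104 mm pixels). Desk-scale work in the tests uses 24 slices on a
  128 x 128 grid with the same field of view.
* **Body**: an ellipse (semi-axes drawn from 165–215 mm by 115–155 mm,
  an obesity-range habitus) with a smooth low-order angular perturbation
  of the boundary. Cross-sectional area rises then falls along the
  craniocaudal axis.
* **SAT**: a ring directly under the skin with angularly varying
  thickness (18–45 mm); its inner boundary is an ellipse shrunk by the
  local thickness, so a uniform ring reproduces the closed-form ellipse
  annulus area to rasterisation accuracy (tested at 2%).
* **Wall and cavity**: an 8 mm muscular wall separates SAT from the
  abdominal cavity.
* **VAT**: 16–32 soft-tissue-free ellipsoid depots (16–52 mm diameter)
  placed in the cavity. Each depot has its own random stream keyed by
  (seed, subject, depot index), so enlarging the depot count extends a
  cohort without reshuffling existing depots — and VAT volume is
  monotone in depot count. Depots are clipped to the cavity and carved
  around organs. With these defaults a full-length series carries
  roughly 8–16 L SAT and 2–4 L VAT (VAT/SAT 0.15–0.35), matching
  whole-abdominal volumes reported for cohorts with BMI >= 35.
* **Confounder organs**: spine (signal 0.50), kidney pair (0.68), bowel
  loops (0.78), bladder (0.30), versus lean tissue 0.35 and fat 1.0.
  Kidneys and bowel deliberately sit in the upper intensity tail near a
  fat/non-fat threshold, so that pure intensity thresholding mislabels
  part of them as visceral fat — the regional misclassification known
  from intensity-based reference methods.
* **Signal model**: in-phase = water + fat, opposed-phase =
  |water − fat| (dual-echo gradient-echo behaviour); a smooth
  multiplicative bias field (±15%) and Rician noise
  (sigma 0.04 on a fat signal of 1.0, SNR ≈ 25) are applied after the
  label map is fixed, so ground truth is exact by construction.

What the phantoms do **not** model: MR relaxometry, chemical-shift and
motion artifacts, partial-volume mixing at tissue boundaries, anatomical
topology beyond ellipses (organ shapes are schematic), arms in the field
of view, and pediatric/low-BMI habitus. Passing tests on phantoms
demonstrates that the pipeline is correct and internally consistent and
that the networks can learn the compartment geometry; it does not
certify performance on patient data.

## Segmentation networks

Three encoder-decoder architectures share a macro-structure (encoder
blocks with 2x2 max pooling, bottleneck, mirrored decoder, 1x1
classification head, softmax over 3 classes):

* **UNet** — double 3x3 convolution blocks, transposed-convolution
  upsampling, skip concatenation.
* **DenseUNet** — densely connected blocks (thin convolutions of
  `growth_rate` channels on the running concatenation, 1x1 transition).
* **CDFNet** — competitive dense fusion: the concatenation is replaced
  by an element-wise maximum over thin candidate features, and the
  decoder upsamples by max-unpooling with index transfer from the paired
  encoder pool, fusing with the skip by maximum.

Because fusion by maximum or by thin dense layers never multiplies
channel counts, both dense variants use far fewer parameters than the
UNet at matched depth and width (about 6.2 M and 1.1 M versus 31 M at
depth 4, base 64 — the classic UNet configuration).

The stack is implemented directly in numpy (channels-last layout,
convolution as one batched matrix product per kernel tap, explicit
backward passes, Adam). Gradients are verified against directional
finite differences for all three architectures in the test suite.

Inputs are single-channel in-phase slices, normalised per slice to
[0, 1] between the 1st and 99th intensity percentiles, and resampled to
the model's square input size; predicted class probabilities are
resampled back to the native grid (bilinear, renormalised) and decoded
by argmax with ties resolving to the lowest class index.

## Training and cross-validation

Folds are assigned at the subject level: k groups; in rotation f, group
f is the test set, group (f+1) mod k validates, the rest train
(60/20/20 at k = 5). Every subject is tested exactly once by a model
that never saw it; the plan invariants are re-validated at run time and
a corrupt plan aborts the run.

The loss is pixel-wise cross-entropy plus macro soft-Dice over the SAT
and VAT classes; both soft-Dice and the default inverse-frequency-style
cross-entropy class weights (0.4, 2.5, 8 for background/SAT/VAT)
counter the heavy background dominance of abdominal slices — without
them the visceral class stays at zero Dice for the first few epochs
before taking off. Training with weighted cross-entropy scales the
learned posteriors by the class weights, which by itself over-segments
the upweighted classes (visceral volume overcalled by ~20% in fold
experiments); prediction therefore divides the posteriors by the same
weights before the argmax (plug-in correction), restoring the
calibrated decision rule. Optimisation uses Adam (lr 5e-3, batch 8),
optionally halving the learning rate over the final epochs
(`lr_decay`, `lr_decay_start`) to settle the class boundary once the
main learning phase is over — decaying earlier stalls the visceral
class. Training can draw random square crops (`crop_size`) instead of
full slices: the networks are fully convolutional, so they predict at
full slice size regardless, and cropping acts as strong translation
augmentation while cutting step cost by the area ratio; in fold
experiments 80 px crops of 128 px slices more than halved per-subject
volume error at equal wall time. Early stopping monitors the mean of
SAT and VAT validation Dice (optionally on a slice subset,
`val_stride`) with the best checkpoint retained; `patience = 0` runs
exactly one epoch, and `min_epochs` keeps early stopping from firing
during the volatile mid-training phase, where a transient validation
plateau can masquerade as convergence. All settings remain
config-exposed for harder data.

Augmentation (when enabled) samples one transform per pair: left-right
flip (p = 0.5), rotation ±10°, scaling 0.9–1.1, translation ±12 px,
elastic deformation (alpha 30, sigma 6, p = 0.3), gamma 0.8–1.25, and
additive Gaussian intensity noise; geometric transforms hit image and
mask identically with nearest-neighbour mask interpolation, so labels
stay in {0, 1, 2} exactly.

## Volumetry

Per-slice class areas (pixel count x pixel area) are integrated with a
through-plane extent of thickness + gap per slice (10.5 mm by default),
treating the unimaged gap as belonging to the slice's sample volume —
the choice that makes contiguous whole-abdomen coverage sum to the
anatomical volume. A gap-exclusive mode is available
(`include_gap=False`) since protocols differ on this convention.
Predictions made on the model grid are resampled to the acquisition
grid (nearest neighbour) before area computation; on phantoms this
round-trip changes per-subject volumes by well under 1.5%.

## Agreement metrics

Volumetric agreement over a cohort uses relative errors
e_i = (pred_i − true_i)/true_i and reports: Pearson R, mean percentage
error (MPE, bias), population standard deviation (SD, variation),
root-mean-square percentage error with the exact decomposition
RMSPE² = MPE² + SD² (the reason SD uses population normalisation), the
second Wasserstein distance of mean-normalised volumes in its
quantile-matched 1-D form, and excess kurtosis (population moments).
Reliability uses ICC in the two-way, single-measure, absolute-agreement
form ICC(2,1) (consistency form behind a flag) and a root-mean-square
within-pair coefficient of variation. Bland-Altman summaries report the
mean relative difference with mu ± 1.96 SD limits. Pixelwise agreement
is overall accuracy plus per-class Dice, with empty-versus-empty Dice
defined as 1 (affects only pathological slices).

The PW2 and CV functional forms are standard-form choices documented
here because more than one convention exists; every metric is checked
against an independent brute-force implementation (and ICC additionally
against `pingouin`) in the tests.

## Threshold baseline

The baseline mirrors intensity-threshold reference methods: body mask
(above-background threshold, morphological closing, largest component,
hole filling), fat/non-fat split by Otsu's criterion on the body
histogram — refined by intermeans (Ridler–Calvard) iteration because
Otsu's criterion has a plateau of optima between well-separated modes
and the bin-edge tie-break can land inside a mode — then SAT/VAT
separation: fat components connected to the body boundary ring are SAT;
fat inside the eroded interior (4 mm margin) is VAT. A manual threshold
override emulates reader adjustment. On noiseless confounder-free
phantoms the baseline is essentially exact; with fat-bright organs
enabled it overcalls VAT, reproducing the known kidney/bowel
misclassification pattern — asserted in the tests as a strict increase
in VAT false positives.

## Problem sizes and numerical choices

The cross-validation analog in the tests and the reproduction script
uses 20 subjects x 24 slices at 128 x 128 with a depth-3 CDFNet
(base 16, growth 16, 3 layers per block, ~82 k parameters), trained for
up to 12 epochs on 72 px crops with the learning rate halved from epoch
9 — sizes chosen so the full 5-fold experiment runs comfortably on a
single CPU while leaving the anatomy, noise and bias-field conditions
at their defaults. Tie-breaks: argmax decoding takes the lowest class index;
max-fusion routes gradients to the first argument on exact ties.
Degenerate inputs: constant slices normalise to zero; empty ROIs and
blank images raise or warn explicitly rather than returning silent
zeros.

## Known limitations

The supplement-level details of the original architectures
(exact channel widths, augmentation hyperparameters, optimiser
schedule) are not public; the configurations here are documented
defaults, not reproductions. Phantom realism is geometric, not
physical; cohort-level numbers obtained on phantoms are analogs, not
re-measurements of any patient cohort. The networks are 2-D and
single-channel; no uncertainty estimation is provided.
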