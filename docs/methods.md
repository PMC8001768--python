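# Methods

This note records the models, parameter choices and numerical decisions
behind `histocompare`, and what the synthetic testbed does and does not
establish about real histopathology data.

## Synthetic H&E-like generator

Patches are rendered with a two-stain Beer-Lambert model: per-pixel
concentrations `c = (c_hema, c_eosin)` and a 3x2 unit-column stain matrix `W`
give `RGB = 255 * exp(-W c)`.  The default `W` uses the common literature
optical-density values for hematoxylin (0.65, 0.70, 0.29) and eosin
(0.07, 0.99, 0.11), column-normalized.  Per-image stain variation is Gaussian
jitter on the matrix entries followed by clipping to non-negative values and
column renormalization.

Nuclei are ellipses (semi-minor axis `r*sqrt(1-e^2)`) whose normalized
boundary radius is perturbed by three low-order sinusoids with random phases,
`r(theta) = 1 + a * sum_k c_k sin(k theta + phi_k)` with `sum c_k = 1`; the
amplitude `a` is the class's margin-irregularity parameter.  Nucleus
interiors carry high hematoxylin concentration; eosin is a band-passed noise
field (the class's texture band, in cycles per patch) representing stroma.
Spatial clustering draws nucleus centers around a reduced number of attractor
points.  Magnification is a pure nucleus-scale multiplier
(40x: 1.0, 100x: 1.6, 200x: 2.5, 400x: 4.0) at fixed patch size, so one knob
changes scale without resampling artifacts.

Class defaults encode the textbook contrast: benign-like classes have small
(radius 3-6 px at 40x), round, smooth-margined, loosely clustered nuclei and
coarse stroma texture; malignant-like classes have larger (6-11 px),
eccentric, irregular, clustered nuclei and finer texture.  Eight sub-classes
(A, F, PT, TA benign; DC, LC, MC, PC malignant) grade these knobs, and twenty
texture classes (A-T) vary mainly the texture band and stain mix for the
960-patch, 308x168 fixture.  Ground truth (nucleus centers, the union mask of
rendered nuclei, and the optional quadrant where all nuclei were confined) is
returned with every image.

**What the generator does not emulate:** real nuclear chromatin texture,
overlapping tissue layers, scanner optics, compression artifacts, annotation
noise, or patient-level correlation structure.  Passing tests therefore
establish implementation correctness and the directional behavior of the
methods under known signal, not clinical performance.  The default classes
are deliberately well separated (a plain threshold on ground-truth nucleus
area exceeds 90% accuracy), so classification accuracies near 100% on this
testbed are expected, not remarkable.

## Stain separation and normalization

Optical density uses base-10 logarithms (`OD = -log10(max(I,1)/I0)`,
`I0 = 255`); the generator renders with base-e, which only rescales
concentrations by `ln 10` and leaves every direction, cosine and
normalization property unchanged.  Tissue pixels are those with max-channel
OD above `beta = 0.15`; images with fewer than 100 tissue pixels raise a
"no tissue" error, which the pipeline logs and answers by passing the image
through unchanged.

The two-stain factorization minimizes `||V - WH||_F^2 + lambda * ||H||_1`
over `W, H >= 0` by multiplicative updates with per-sweep column
normalization, entries floored at 1e-4 (zero is an absorbing state of
multiplicative updates), at most 200 sweeps and a 1e-6 relative-objective
stop.  `lambda = 0.02` in these units; published defaults for the
natural-log, per-pixel-averaged form of the same objective are numerically
larger.  The penalty must stay mild: without pure-stain pixels the problem is
only weakly identifiable, and a strong penalty provably tilts the optimum's
hematoxylin column toward the mixed nucleus direction (observed cosine ~0.71
against the generating matrix at five times the default penalty).

Initialization is geometric rather than random: tissue ODs are projected onto
their dominant 2-D plane (SVD) and the robust angular extremes (1st/99th
percentile) of the pixel cloud give the initial stain directions — the edge
rays of the stain cone, which are the quantity of interest.  The budgeted
multiplicative refinement then improves reconstruction without drifting away
from the cone; deterministic throughout (the seed argument only covers a
degenerate-geometry fallback).  Hematoxylin is the column with the larger
blue-channel loading.  Concentration maxima (`c_max`, 99th percentile) and
the recomposition concentrations use unpenalized non-negative least squares:
the L1 term is a device for estimating `W`, and carrying its shrinkage into
reconstruction would bias self-normalization (observed mean absolute error
drops from ~8 to ~0.03 intensity levels).  The reference image is a
configuration input; no automatic template selection is attempted.

## Handcrafted features

Gray conversion is ITU-R BT.601 luma.  Images are resized to 224x224 before
extraction so both classification arms see identical inputs; the resize
target is configurable and property tests that only need relative behavior
use 64 to stay fast.

*Zernike*: the image grid maps onto the unit disk centered at the image
center with radius `min(H, W)/2`; pixels outside contribute zero.  The
normalization constant is the count of pixels inside the disk, which makes
`|Z_00|` the disk-mean intensity and bounds all magnitudes.  Magnitudes (not
complex values) are returned — only magnitudes are rotation-invariant.  For
`n_max = 8` there are exactly 25 valid (n, m >= 0) pairs.

*GLCM/Haralick*: gray values are uniformly quantized to 32 levels over
[0, 255]; co-occurrences are counted at displacement
`(round(d cos a), -round(d sin a))` in (column, row) terms — the mathematical
angle convention with y up; a library using row-down angles gives the same
symmetric matrices under angle negation.  Distances {1, 2, 4} span fine to
coarse texture at 224x224.  The 13 classical statistics (the unstable 14th is
omitted) are computed per matrix with log base 2 and a 1e-12 additive guard
inside entropy terms, then averaged element-wise over all 24
distance-angle combinations.  Correlation is defined as 0 when either
marginal standard deviation vanishes (constant image).

*Color histogram*: the joint 8x8x8 RGB histogram (512 bins) rather than three
concatenated 8-bin marginals — the joint form is what yields a 512-long
vector — flattened R-major and normalized to frequencies so the feature is
resolution-independent.

## Classical classification protocol

Stratified k-fold (default 10) with shuffling; within each fold's training
portion a stratified 30% validation split is held out.  Features are
standardized with training-fold statistics only.  The validation split is
scored for monitoring and recorded in the results; the scikit-learn MLP
cannot consume an explicit validation set, so no selection decision depends
on it (all classifiers fit on the training portion and are evaluated on the
untouched test fold).  Metrics are accuracy and macro-averaged recall and
precision (equal class weight — the defensible default for imbalanced
sub-classes), in percent; per-fold values and their arithmetic mean are both
reported.  KNN uses Euclidean distance (the metric is configurable), and
splitting is image-level by default with patient-grouping available where
leakage-free protocols are wanted.

## Network arm

The numpy implementation is a compact CNN written for this package: im2col
convolutions, argmax-tracked 2x2 max-pooling, inverted dropout, He-style
seeded initialization, softmax cross-entropy, and SGD with momentum where
weight decay applies to weights only (not biases).  Gradients were verified
against central finite differences at build time.  Determinism per seed is
exact: the seed fans out to separate generators for splitting, shuffling,
augmentation and dropout.

Inputs are standardized by training-split channel statistics, stored on the
network so fine-tuning, feature extraction and Grad-CAM share one scaling
(a transferred backbone keeps its source statistics).  A fixed 0.5/0.5
scaling is available but mostly-white histology patches then sit far from
zero and cost several of a short run's epochs in a dead plateau.

Fine-tuning follows the fixed protocol (momentum 0.9, learning rate 1e-3,
weight decay 1e-3, dropout 0.5, batch 32, stratified 70/30 split, final-epoch
model — no early stopping; constant learning rate).  Augmentation is online:
one of {identity, h-flip, v-flip, rot90, rot180, rot270} drawn per sample per
epoch; rotations require square inputs.

Block-wise fine-tuning presupposes a pretrained source.  At desk scale the
package pretrains its own: `pretrain_backbone` trains a miniature instance on
the eight-subclass x four-magnification synthetic task (640 images).  The
source protocol — learning rate 0.01, dropout 0.2, 40 epochs — is the
package's choice for the source domain; the target protocol above is never
altered.  `transfer_weights` copies everything except the final classifier.
Structural and freeze tests run from seeded random initialization; only the
classical-vs-deep comparison uses the pretrained source, because comparing a
~135-update random-initialized network against converged classical learners
would not exercise a transfer-learning design at all.

Desk-scale study conditions: 400 images (200 per class) at 64x64, network
scale factor 8, 15 fine-tuning epochs, three seeds.  64x64 is the smallest
size at which the default classes' nuclei do not saturate the patch and all
twenty texture bands stay below Nyquist.  Under these conditions the
fine-tuned arms and the best classical arms both sit at or near 100%
accuracy — the synthetic task has a ceiling, and the meaningful claims are
directional (deep >= best classical; deeper schedules >= head-only), not the
margins between them.

The planted-signal localization experiment (all nuclei confined to one
quadrant) is a *detection* contrast — quadrant-of-nuclei versus no-nuclei —
rather than a location contrast: under the protocol's flip/rotation
augmentation a TL-versus-BR location task is unlearnable (rot180 maps one
class onto the other), and even without augmentation the network's faithful
evidence for "nuclei in TL" includes the emptiness of the other quadrants,
which Grad-CAM then rightly highlights.  With the detection contrast,
augmentation makes the learned features position-agnostic, so the heat
follows the nuclei.  Patches are 96x96 there: the last convolutional layer's
6x6 map resolves a quadrant, while at 64x64 the 4x4 map is too coarse.

## Explanation stack

PCA uses a full SVD with the largest-loading-positive sign convention so
plots are reproducible; kernel PCA uses a dense double-centered kernel
eigendecomposition with gamma = 1/p for rbf/sigmoid and degree 3 / coef0 1
for the polynomial kernel (the linear kernel reproduces PCA up to component
sign).  Embeddings are fitted per data subset (e.g. per magnification), not
pooled.

Grad-CAM targets the last convolutional layer's post-ReLU feature maps
regardless of the freeze schedule; weights are spatial means of the
pre-softmax class-score gradient, the weighted sum is rectified, bilinearly
upsampled (nearest-neighbor available) and min-max normalized to [0, 1], with
identically zero maps returned as zeros rather than dividing by zero.
Overlays blend a blue-to-red colormap at a configurable opacity.

## Pipeline

One master seed fans out to per-stage seeds through a fixed CRC-based hash.
Stages write their outputs (dataset, normalized images, feature table,
per-arm results, report) under the run directory and are skipped when those
outputs exist, so interrupted runs resume and repeated runs are byte-stable
(no timestamps inside reports).  Per-cell failures (e.g. a class with fewer
records than folds) are recorded in the report with their error text while
independent cells proceed.  Arm selection follows accuracy, with ties broken
by macro recall, then lexicographic arm id.  Both arms consume the same
stain-normalized images.

## Known limitations

Pure-numpy training is practical only at miniature scale; full-scale
(scale_factor 1, 224x224) training is out of reach on a single CPU, and
full-scale use is limited to structural checks and single forward passes.
The stain model assumes exactly two stains and no chromatic aberration.
The generator's separability ceiling means comparative accuracy differences
between strong methods compress toward zero; conclusions about real tissue
require real data.
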