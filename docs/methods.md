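# Methods

## Model

The segmentation model is a pair of UNet encoder–decoders applied in
sequence. Each UNet level applies two 3×3 convolutions (ReLU, optional
batch normalisation) followed by 2×2 max pooling on the way down; the
decoder mirrors the schedule, upsampling either with a learned 2×2
transposed convolution or with nearest-neighbour interpolation followed by
a 3×3 convolution, concatenating the same-level encoder features (skip
connection), and applying two more convolutions. A 1×1 convolution with
sigmoid activation produces a soft mask.

The second UNet differs from the first in two ways only:

1. its input is the channel concatenation of the image and the first
   UNet's *soft* mask (4 channels). The soft mask is used rather than a
   binarised one so the whole graph stays differentiable through the first
   head;
2. after each of its encoder blocks, after its bottleneck block, and after
   each of its decoder blocks, its feature maps are replaced by the
   elementwise mean of themselves and the first UNet's corresponding maps.
   The mean is implemented exactly as `(a + b) / 2`; the averaging reading
   of the level-fusion rule is adopted (the alternative reading `a + b/2`
   is rejected because the surrounding description speaks of *averaging*
   features at every fusion site). Skip connections in the second UNet
   carry the fused maps.

Both heads are supervised with equal weight during training, since the
quality of both masks is part of the model's contract.

## Default schedule and the parameter-count target

The published account of the full-scale model fixes the optimiser (Adam),
learning rate (0.005), batch size (32) and the trainable-parameter total
(1,081,942) but not the depth, filter counts, normalisation or upsampling
mode. The default configuration is therefore fixed by an exhaustive
constraint search (`scripts/search_default_config.py`, logic in
`dhunet.search`) over standard dual-UNet schedules: depth 2–5, base
filters 4–32, batchnorm on/off, and both upsampling modes, under the
package's layer conventions (block convolutions drop their bias when
followed by batch normalisation; batchnorm contributes a scale and a shift
per channel; upsampling convolutions and heads keep biases).

No enumerated schedule reaches 1,081,942 exactly. The closest is depth 4,
base 8 filters, batchnorm on, interp+conv upsampling, at **1,081,978**
parameters — 36 over the target (0.003%). That configuration is frozen as
the default, and the package's quantitative criterion is the equivalence
of the built model's count with an independent closed-form layer
enumeration; the 36-parameter discrepancy against the published figure is
accepted and documented here rather than hidden by adjusting conventions
until the number matches.

## Numerical engine

No deep-learning framework is required: `dhunet.nn` is a small
reverse-mode autodiff engine on numpy arrays. Convolutions use im2col plus
BLAS matrix multiplication; the input gradient is computed as a
convolution with the channel-transposed, spatially flipped kernel, and the
weight gradient reuses the cached im2col matrix. Max-pool backward routes
gradients through argmax indices (first maximum wins ties). Batch
normalisation uses batch statistics during training (momentum 0.1 running
averages, epsilon 1e-5) and the running averages at evaluation. Every
operation's gradient is verified against central finite differences in
float64 in the test-suite.

Losses clip probabilities to [1e-7, 1 − 1e-7] for the cross-entropy and
use a 1e-6 smoothing constant in the soft Dice, which also defines the
Dice of two empty masks as 1. For evaluation, 0/0 is defined as 0 for
precision, recall and F1. Predictions are binarised at 0.5 with the ≥
convention. Metric aggregation defaults to pooled pixel counts over the
whole evaluation set (micro); a per-image macro mean is also computed and
labelled, since the published tables do not state their aggregation.

Initialisation is He-uniform from a seeded generator; with a fixed seed,
initial parameters, shuffling, and therefore entire training histories are
bit-reproducible on one machine.

## Preprocessing

The region-of-interest pipeline is: ITU-R 601 luminance conversion; median
blur (kernel 5 by default; a Gaussian mode with a normalised discrete
kernel honours the alternative smoother); binarisation at a fixed low
threshold (default 10 of 255 — the artifact being removed is near-black,
so a low global threshold separates content from border bands); connected
8-neighbour region labelling; marching-squares boundary tracing snapped to
boundary pixels; selection of the largest region by pixel-centre shoelace
area; Douglas–Peucker simplification at 1% of the contour perimeter (the
simplified polygon's farthest-from-centroid vertex and maximal x/y
coordinates are exposed for inspection); cropping image and mask with the
contour's axis-aligned bounding box; bilinear image resize to the target
size with [0, 1] scaling and nearest-neighbour mask resize re-binarised at
0.5.

The bounding-box crop rule is a design choice: the source description
names a farthest point and maximal coordinates without giving the box
formula, and the bounding box is the minimal reading that removes border
bands while keeping all content. When no contour is found (an all-black
frame) the identity crop is used so no sample is silently discarded.
Border handling in both blur filters replicates edge pixels; mirrored
borders would bleed interior content into one-pixel black bands and break
the exact band/content separation.

Coordinates are 0-based with x = column; crop boxes are half-open. The
binarisation uses a strict `> threshold`.

## Synthetic data

The generator emulates the features of wound photographs that the pipeline
depends on: a skin-toned background (default RGB (198, 144, 118)) with
Gaussian pixel noise (sd 8) and a low-amplitude smooth illumination field;
one to three lesions, each an ellipse (aspect 0.6–1.0, random orientation,
radius 8–25% of the frame) whose radius is modulated by a sum of four
random-phase sinusoids scaled by a jitter parameter (default 0.3) — the
supports are star-shaped, hence simply connected, and the mask is their
exact union; lesion colour is reddish (R 140–200, G 30–70, B 35–75),
well separated from skin; optional all-black border bands of given widths.
Geometry is drawn in unit coordinates from a random stream separate from
the texture stream, so a seed fixes the same scene at any raster size and
foreground fractions are scale-free to within rasterisation error.
Per-sample seeds in datasets derive from the template seed and the sample
index through a counter-based seed sequence, so regeneration is
order-independent and byte-identical.

What the generator does **not** emulate: real lighting variation, specular
highlights, camera blur, multi-class tissue types, wounds touching the
frame edge, and realistic lesion-size distributions (no public
characterisation of the benchmark's statistics exists). A green end-to-end
test therefore establishes that the architecture, objectives and pipeline
work and interact correctly — not clinical-grade performance on
photographs.

## Desk-scale experiments and their scope

The test-suite trains reduced models only: depth 3, base 4 filters (67,486
parameters, no batchnorm so evaluation does not depend on slowly converging
running statistics) on 64 synthetic 64×64 samples for 30 epochs, with a
held-out head-2 Dice ≥ 0.70 gate under both strategies; and an
overfit-sanity check of 50 Adam steps on a fixed 8-sample batch halving
the combined loss. The published full-scale benchmark numbers (e.g.
precision near 90% on the public foot-ulcer test split) require the real
dataset and GPU-scale training and are deliberately **not** reproduced or
asserted here.

The direction of the strategy trade-off — training with the Dice objective
yields equal or higher head-2 precision than training with cross-entropy —
is checked across ten seeded micro-runs (24/12 train/test samples at
32 px, 40 epochs at batch 8, enough steps for both objectives to converge;
under-trained cross-entropy runs collapse to all-background predictions
and make the comparison meaningless), requiring at least 7 of 10 runs in
the stated direction, together with the weak-form guarantee that the Dice
strategy never trails the cross-entropy strategy's training-set Dice by
more than 0.05.

## Known limitations

* CPU-only and numpy-based: full-scale (128 px, million-parameter,
  hundreds of images) training is possible but slow; the package is built
  for desk-scale verification and architectural study.
* Batch-norm evaluation quality depends on running statistics; very short
  trainings should disable batchnorm (the reduced config does).
* The contour tracer targets filled regions; one-pixel-wide structures are
  assigned zero area and only win when nothing larger exists.
* Checkpoints are numpy archives tied to this package's layer naming; no
  interchange format is provided.
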