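# Methods

## Scope and design

The package implements a one-class tissue-classification pipeline for skin
OCT B-scans: a 4-class segmentation U-Net doubles as a per-pixel feature
extractor, a one-class SVM trained only on normal tissue scores image
patches, and a wavelet-filtered score trace localizes normal/abnormal
boundaries. All stages are exercised on synthetic phantoms so the full
chain is testable without clinical data. This note records the model
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Phantom model

A phantom B-scan is a noise-free layer template multiplied by i.i.d.
unit-mean Rayleigh speckle. Axis 0 is depth (row 0 at the air side, 5 µm
per pixel), axis 1 is the lateral scan (17 µm per A-scan). The template:

* air above the surface at a constant noise floor (`intensity_air`, 0.04);
* stratum corneum, `sc_thickness` (2–5 px) rows at the brightest level
  (`intensity_sc`, 1.0);
* epidermis at reduced brightness (`intensity_epidermis`, 0.55) down to the
  dermis–epidermis junction (DEJ);
* dermis decaying as `intensity_dermis_top * exp(-d / dermis_decay_length)`
  with d the depth in pixels below the DEJ.

Magnitudes are linear throughout; all anomaly operators act on linear
magnitude. Intensities are on an arbitrary scale fixed by
`intensity_sc = 1`. The defaults are not calibrated to any particular
instrument — the source system's intensity statistics are not numerically
characterized — but are chosen so the canonical appearance holds: thin
bright entry layer, dimmer epidermis with a visible DEJ, dermis signal
decaying with depth yet remaining above the noise floor across the 1.28 mm
image. `dermis_decay_length` defaults to 120 px (0.6 mm), consistent with
skin attenuation at 1060 nm (µ_eff ≈ 1–2 mm⁻¹); with a much shorter decay
the lower half of the phantom would be indistinguishable from noise and
deep anomalies would be unlearnable in principle.

The surface undulates along x as low-pass-filtered Gaussian noise rescaled
to ±`surface_undulation_amp` (6 px) and quantized to integer rows, giving
the network a nontrivial DEJ geometry. Multi-image datasets jitter layer
*thicknesses* per image (epidermis ±20%, stratum corneum 2–5 px, surface
depth ±20%) under per-image child seeds spawned from one dataset seed;
layer intensities and the decay length are held at their nominal values —
they describe tissue/instrument optics rather than anatomy, and the
abnormality operators are defined as magnitude changes against that
nominal appearance.

What the phantom does *not* model: spatially correlated speckle (real
speckle has a resolution-cell correlation length; ours is white),
refraction and beam geometry, depth-dependent focus, layer-internal
texture, and real anatomical variability beyond thickness jitter. Passing
tests on phantoms therefore demonstrate the pipeline's mechanics and
internal consistency, not clinical performance.

## Segmentation network

Five encoder stages ([3x3 conv, ReLU] x2 + max-pool, channels
16/32/64/128/256) and five decoder stages. On a 32-pixel-wide input five
poolings are impossible (the lateral axis would reach width 1), so the
fifth encoder stage omits its pool and serves as the bridge; the first
decoder stage mirrors it at bottleneck resolution without upsampling, and
the remaining four upsample (nearest-neighbour x2 + 3x3 conv halving
channels), concatenate the matching encoder skip, and apply two 3x3
convolutions. All convolutions are same-padded so the output label map is
full-size; the last decoder stage emits 16 channels, and its final ReLU
activations are the per-pixel features reused downstream; a 1x1
convolution maps them to the 4 class scores. Ties in the per-pixel argmax
resolve to the lowest class index (air).

Input representation: linear magnitudes are log-compressed at the network
input (`log10(x + 1e-3)`), the conventional domain for OCT image
processing and display. This matters for anomaly sensitivity: a
multiplicative magnitude change (the BCC/SCC operators) becomes an
additive shift visible at every depth, instead of scaling with the local
signal and vanishing in the dim deep dermis. The transform is recorded in
`UNetConfig` (`input_transform`; `"linear"` is available).

Training: pixelwise cross-entropy (optionally class-weighted; off by
default, matching the stated loss), Adam with learning rate 1e-3,
mini-batch 40, 10 epochs by default. All kernels are NumPy with seeded
initialisation and shuffling, so training is bit-reproducible; the
convolution lowers to one BLAS matmul per kernel offset (shift-and-
accumulate), and the backward pass uses the flipped-kernel convolution
identity for input gradients. Gradients are validated against finite
differences in the test suite.

Fixture scale: phantom segmentation is an easy task; 32 patches for 20
epochs of batch 8 reach ~0.99 held-out pixel accuracy in ~2 minutes on one
CPU, and that is the scale used by the tests and the benchmark default.

## Feature pooling

Per-patch predictors are means of the 16 per-pixel activations over pixel
groups of the network's own segmentation (never the ground truth):
`all` = every non-air pixel (stratum corneum included), `epidermis`,
`dermis`, and the 32-dimensional concatenation `[X_e; X_d]`. The mean —
not the raw sum — is used so patches with different layer thicknesses are
comparable; a sum would scale with group size. Air is excluded because
those pixels are noise-dominated; stratum corneum is excluded from the
single-layer groups because very few pixels carry that label. An empty
group raises a degenerate-patch error rather than returning zeros, so
dataset builders must decide explicitly (the batch featurizers skip such
patches with a warning).

## Abnormality operators

* **BCC-like**: one onset row per patch, drawn uniformly from the patch's
  dermis depth range; every pixel at or below it is scaled by 0.75. A
  single shared onset (not per-column) reflects the laterally coherent
  shadowing of nodular BCC.
* **SCC-like**: one axis-aligned rectangle (height 20–60 px, width 8–24 px
  by default — the source describes only "discrete bright regions", so the
  simplest geometry is used), placed uniformly subject to lying fully
  below the detected skin surface, scaled by 1.25.
* **DEJ disruption**: every A-scan is divided by the image's mean depth
  profile and rescaled by the profile's mean, erasing the layer structure
  while preserving the overall mean magnitude (so the classifier must
  respond to structure, not global gain); ε = 1e-6 x max guards zero rows.

Scaling factors of exactly 1.0 are admitted and return the input bitwise
(structural identity). The 4-way dataset builder emits each normal patch
plus its three variants (4x expansion; 1116 normals give 4464 patches),
with all operator randomness drawn from one child stream per patch.

## One-class SVM

Features are standardized per feature (training mean/std); the RBF kernel
scale s is the median pairwise Euclidean distance over a seeded subsample
of at most 1000 standardized training rows (the source names an
"automatic" scale without defining it), with gamma = 1/(2 s²). The
"outlier fraction" maps to nu of the nu-formulation, which upper-bounds
the fraction of training points treated as outliers; the default is 0.08.
Scores are signed decision-function values — distance-like quantities, not
probabilities; only their sign is interpreted (positive = normal, exact
zero counts as abnormal). Image-level classification averages the eight
patch scores of a 256-A-scan image and applies the same sign rule.

## Boundary detection

The score trace (sliding 32-A-scan window, stride 1 by default; stride 32
reproduces the non-overlapping patch workflow) is denoised by soft
thresholding in the wavelet domain: Daubechies-4, decomposition level
min(3, floor(log2 n) - 2), universal threshold sigma*sqrt(2 ln n) with
sigma the finest-detail MAD / 0.6745, periodized boundaries. The exact
wavelet family, level and threshold are unreported in the source;
these are standard defaults and are configurable. Boundaries are local
extrema of |first difference| of the filtered trace above `min_jump`;
the default `min_jump` is half the 95th percentile of |d| — preferably
measured on normal-only traces (`default_min_jump`), falling back to the
trace's own percentile when no normal reference is supplied. Boundary
position is the midpoint of the two samples spanning the jump; direction
follows the sign (falling score = normal→abnormal).

## Evaluation protocol

The benchmark generates 35 phantom B-scans of 2048 A-scans (64 patches
each, 2240 total — approximating the 2232-patch scale of the original
protocol), splits patches 50/50 (train size = ceil(f n)), trains the
segmenter on a 32-patch subset of the *training* half (the original
protocol derived network and classifier from one image pool; the test half
is never seen), pools features for all four groups from a single forward
pass per patch, trains one one-class SVM per group at nu = 0.08, expands
the held-out half into the 4-way test set, and reports per-group ROC AUC
(rank formulation, NORMAL as the positive class, ties counted 1/2),
accuracy at the zero-score threshold (never tuned), confusion counts,
per-anomaly-class detection rates, and the outlier-ratio sweep over
nu ∈ {0.02, 0.05, 0.08, 0.15, 0.20} on the normal test features.

Problem sizes used by the test suite: the segmenter fixture trains on 32
patches from 4 phantom images; the feature bank holds 1000 pooled rows
from 16 images; the benchmark runs at the full 2240-patch scale. The whole
suite completes in roughly 10 minutes on one CPU.

## Known limitations

* Detection of the synthetic SCC operator through mean-pooled features is
  intrinsically limited: a 20-60 x 8-24 px rectangle scaled by 1.25
  shifts a layer-mean feature by far less than the per-pixel speckle
  modulation it competes with, and the shift points along a direction
  (overall dermis brightness) in which normal patches already vary, the
  hardest kind of displacement for a one-class boundary. The 4-way pooled
  AUC of the phantom benchmark is correspondingly dominated by the DEJ
  (easy) and BCC (moderate) classes, while SCC detection stays close to
  chance at the default operating point.
* The feature extractor's sensitivity to amplitude anomalies depends on
  how far segmentation training is pushed: longer training on more
  geometries yields more brightness-invariant activations and weaker
  anomaly response. The fixture recipe (32 patches, 20 epochs) keeps the
  activations in a responsive regime while reaching ~0.99 segmentation
  accuracy; this coupling is a property of reusing a segmentation network
  as a feature extractor.
* One-class scores are uncalibrated; magnitudes are not comparable across
  retrainings, only signs and rankings are.
* The pipeline assumes the canonical layer ordering (air / SC / epidermis
  / dermis); it is not applicable to glabrous nail-plate imaging or
  mucosa without retraining.
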