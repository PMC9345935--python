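# Methods

`karstseg` maps fragmented wetland vegetation from RGB orthomosaics with an
ensemble of one-vs-rest pixel classifiers. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not establish.

## The classification model

Each classifier is a symmetric encoder–decoder ("SegNet-style") network. An
encoder stage is a block of 3×3 convolutions, each followed by batch
normalization and ReLU, ending in 2×2 max pooling that records the argmax
index of every pooling window. The decoder mirrors the encoder: each stage
upsamples by placing values back at the recorded indices (index unpooling,
which re-localizes features exactly rather than interpolating) and applies a
mirrored convolution block. A final convolution produces per-pixel class
scores; softmax turns them into probabilities.

Two deliberate deviations from the canonical architecture:

* **Configurable depth.** The default "desk" variant uses 3 stages × 2
  convolutions at base width 16 — small enough to train on one CPU core in
  tens of seconds. `ArchitectureConfig.full()` provides the canonical
  13-convolution encoder for users with the hardware to train it. Exact layer
  counts are a free parameter of the approach, not part of its substance.
* **Reflect-padded convolutions.** Convolutions pad borders by reflection
  rather than zeros. Zero padding gives every training patch an artificial
  dark frame; models trained on small patches then misbehave on the large
  context tiles used at inference (we measured whole-scene accuracy ~0.17
  below held-out patch accuracy for the multi-class model). Reflection
  removes the mismatch entirely and is consistent with the reflection
  convention used everywhere else in the package (tiling, GLCM borders,
  mirror expansion).

Single-class (one-vs-rest) models are ordinary 2-way softmax networks over
{background, foreground} rather than single-sigmoid heads, so every model in
the system — binary or multi-class — is trained with the same categorical
cross-entropy loss and emits calibrated class probabilities that fusion can
consume uniformly.

## Training

Stochastic gradient descent with momentum, with the published settings as
defaults:

| parameter        | default | meaning                                        |
|------------------|---------|------------------------------------------------|
| learning rate    | 0.001   | initial SGD step size                          |
| gamma            | 0.1     | learning-rate multiplier applied each step     |
| step size        | 1000    | iterations between learning-rate steps         |
| momentum         | 0.8     | velocity coefficient                           |
| weight decay     | 0.0001  | L2 penalty on all weights                      |
| batch size       | 8       | patches per minibatch                          |
| epochs           | 5       | full passes over the training split            |

All randomness (initialization, shuffling, patch sampling, augmentation)
derives from explicit integer seeds, and two runs with the same seed are
bit-identical.

**Desk-scale protocol.** The original workflow trains on ~10⁵ patches of
256×256 px; on one CPU that is out of reach. At a fixed learning rate the
quantity that drives convergence is the number of SGD iterations, not the
patch area, so the desk protocol trades one for the other at constant pixel
throughput: 16×16 px patches sampled densely from the scene (1700 patches for
binary tasks, 3400 for the five-class task; 75/25 train/test split). This
yields 800–1600 iterations in 15–30 s per model and held-out accuracies above
0.95 on binary tasks. Note the interaction with the schedule: with step size
1000, runs longer than ~2000 iterations learn almost nothing further, which
bounds the useful dataset size at this scale. The patch extractor rejects and
redraws any window touching nodata, so the loss needs no mask handling.

**Augmentation.** Flips, right-angle rotations, seeded per-channel color
shifts (±25 DN), random rescaling (factor 0.8–1.25, nearest-neighbour label
resampling, center crop/reflect-pad back to size) and RGB inversion.
Geometric operations transform image and label identically; radiometric ones
leave the label untouched.

## Texture features

Per-pixel grey-level co-occurrence (GLCM) statistics: the source band
(luminance of RGB by default) is min–max quantized to 64 levels; for each
pixel a symmetric normalized co-occurrence matrix is accumulated over all
pixel pairs inside the centered window (3×3, 5×5 and 7×7 by default) related
by the four distance-1 offsets (0°, 45°, 90°, 135°, pooled); eight Haralick
statistics are evaluated — mean, variance, homogeneity, contrast,
dissimilarity, entropy, second moment, correlation (defined 0 where the
window variance vanishes, since the ratio is otherwise undefined). Borders
reflect the band. Each feature map is min–max rescaled to [0, 255] and
appended as an extra scene channel — 24 channels for the full default — so
texture enters the classifier exactly like color does.

The implementation is a compiled (numba) per-pixel accumulation; the test
suite checks it to 1e-10 against an independent pair-enumeration oracle and
against `skimage.feature.graycomatrix` on single windows.

## Seamless whole-scene inference

Classifying a mosaic in independent tiles and abutting the results leaves
visible seams wherever a pixel near a tile edge was classified without its
real surroundings. The remedy: cut the scene into *core* tiles (128 px),
classify an enlarged *context* window (256 px) around each, keep only the
central core of every prediction, and stitch cores. If the margin
(context − core)/2 is at least the classifier's receptive field, the stitched
map is *identical* to a single whole-image pass at every pixel farther than
the receptive field from the scene border — a property the tests verify
exactly with mock classifiers of receptive field 1–33 px. (The desk
architecture's receptive-field bound is 33 px, within the default 64 px
margin.)

Design choices where the procedure was underdetermined:

* Context is taken from the real neighboring pixels of the padded scene;
  mirror reflection is used only at the outer scene border. The literal
  variant that mirror-expands every core tile independently is available as
  `mode="per_tile_mirror"` — it fabricates context at interior tile edges and
  demonstrably deviates from the whole-image pass there.
* Scenes whose sides are not multiples of the core size are reflect-padded up
  and the output cropped back.
* Stitching operates on probability maps, with the argmax taken once at the
  end, so no quantization happens at seams and fusion downstream consumes
  consistent probability fields. The naive abutting-tile baseline
  (`predict_naive`) is kept for demonstrating and regression-testing the seam
  artifact.

## Maximum-probability fusion

Each one-vs-rest model contributes its foreground probability for its own
class; per pixel the fused label is the class of maximal foreground
probability, ties to the lowest class id. Because a single-class model
carries no evidence about other classes, each class's score has exactly one
contributing model; background probabilities are not redistributed.

The vegetation models cover only the vegetation classes, yet real maps
contain an "other types" category. The package handles this with an explicit
confidence threshold τ (default 0.5): a pixel whose best foreground
probability falls below τ is assigned the designated other class. This is an
interpretation — the original formulation is silent on how non-vegetation
pixels enter the fused map — and both τ and the other class are configurable.

## Accuracy assessment

The error matrix (reference classes in rows, predicted in columns) is built
from ground-truth point samples or from a reference raster over jointly valid
pixels. From it: overall accuracy (trace/total), the kappa coefficient
((p_o − p_e)/(1 − p_e) with p_e the chance agreement of the marginals), and
per-class precision (= user's accuracy), recall (= producer's accuracy) and
F1. One-vs-rest models are assessed on the 2×2 matrix after collapsing both
sides to foreground/background, including a binary kappa. Ratios with empty
denominators are reported as an explicit undefined flag, never silently as
zero, so class averages are not distorted; kappa is undefined when p_e = 1.

## The synthetic test bed

No imagery from the original study is publicly deposited, so the package
ships a generator that emulates the properties that matter to the method:

* **Patch geometry.** One smoothed Gaussian noise field per class; the
  per-pixel argmax over fields produces contiguous but irregular, fragmented,
  intersecting patches. The smoothing length `patch_scale` (default 40 px) is
  the single fragmentation knob — component size grows monotonically with it.
  An "other types" class is carved out at an exact target fraction (default
  12%) by thresholding its field at the matching quantile.
* **Radiometry.** Class mean color + white Gaussian noise + an optional
  texture pattern (oriented sinusoidal stripes, or smoothed-noise speckle),
  clipped to [0, 255]. The default five classes are loosely styled on open
  water, grassland, broad-leaved canopy, floating aquatic flora and
  agriculture/bare ground.
* **Texture pairs.** For isolating the value of texture channels, a recipe
  with two classes of identical color statistics and variance-matched speckle
  of different grain (0.7 px vs 3 px). On the fixed seeds the per-class
  luminance histograms overlap (KS distance 0.03) while window-7 GLCM
  contrast separates the classes by >3 pooled standard deviations. A
  roughness contrast is used rather than a pattern contrast (stripes) because
  a convolutional classifier learns periodic patterns from raw RGB quickly,
  which would leave precomputed texture channels nothing to add at the desk
  training budget.
* **Mock classifiers.** Nearest-mean-color rules, optionally on an r×r window
  mean, with an exactly known receptive field and label-smoothed one-hot
  probabilities. These are the oracles for the seamlessness guarantees and
  for fusion consistency tests (on noise-free renderings the nearest-color
  rule reproduces the labels exactly).

What passing tests show — and what they do not: the synthetic scenes exercise
the pipeline's correctness (stitching identities, fusion arithmetic, metric
definitions, convergence of the training loop) and reproduce the two
qualitative findings (a fused one-vs-rest ensemble is at least competitive
with a jointly trained multi-class model at an equal budget; texture channels
do not hurt, and help when color is uninformative). They do not emulate real
UAV radiometry, georeferencing error, phenology, mixed pixels or class
imbalance at survey scale, so absolute accuracy values measured here say
nothing about accuracy on real mosaics.

## Numerical notes and limitations

* The network runs in float32; forward/backward passes were verified against
  numerical differentiation. Softmax rows sum to 1 within 1e-6.
* Quantization is range-relative (min–max of the valid pixels), so GLCM
  features are invariant under adding a constant to the band. A constant band
  quantizes to all zeros; its GLCM is the single-cell distribution (contrast
  0, homogeneity 1, entropy 0, second moment 1).
* Argmax ties (fusion and labeling) resolve to the lowest class id,
  deterministically.
* The learning-rate step every 1000 iterations means desk-scale runs beyond
  ~2000 iterations stop improving; at full scale the same schedule behaves
  differently (the published runs take ~10⁴–10⁵ iterations per epoch). The
  step size is configurable.
* Conditional-random-field post-processing and label-production pipelines
  (object-based segmentation + random-forest labeling) are out of scope; the
  package consumes ready label rasters.
* Checkpoints are NumPy archives plus JSON metadata (architecture, training
  config, target class, receptive-field bound); they are runtime artifacts,
  not portable across package versions.
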