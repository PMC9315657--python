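# Methods

This note documents the models and numerical choices behind `mribovw`:
what each stage computes, which parameters matter, what the phantom
generator does and does not emulate, and where the design was genuinely
open.

## Grayscale conversion and dataset handling

Colour rasters collapse to luminance with the fixed ITU-R 601 weights
(0.299, 0.587, 0.114); 8-bit inputs divide by 255, float inputs already
in [0, 1] pass through, and float inputs on other scales are min-max
rescaled per image.  No dataset-level statistics enter the conversion,
so a single image converts identically regardless of its neighbours.
Images are never resized by default.  Dataset enumeration is
lexicographic by class folder then filename, which makes vocabulary
construction independent of filesystem ordering.

The stratified split assigns `round(f·n_c)` of each class's `n_c`
images to training (default f = 0.8), clamped so both sides keep at
least one item; the permutation is driven only by the split seed.

## Gaussian-family descriptors

An integral image answers axis-aligned box sums in four lookups.  Two
extensions matter at borders and between pixels:

* **Area-normalized clamping.**  Rectangles reaching past the border
  are clamped, and the clamped sum is rescaled by
  nominal-area / clamped-area.  This keeps multi-lobe filters balanced
  at the border: a constant image produces exactly zero derivative and
  Hessian responses everywhere, including corners.
* **Fractional rectangles.**  The running integral of a
  piecewise-constant image is exactly bilinear inside each unit cell,
  so bilinear interpolation of the integral table integrates
  real-valued rectangles exactly.  Descriptor sample points therefore
  need no rounding to the pixel grid, which makes the descriptor of a
  2×-upsampled image at 2× scale agree closely with the original (the
  scale-consistency property the tests assert).

The Hessian determinant uses the classic box-filter approximations of
the second Gaussian derivatives: filter side `L = 3·lobe` with the lobe
rounded odd from `σ/1.2·3`, responses scaled by `1/L²`, and the
determinant `Dxx·Dyy − (0.9·Dxy)²` with the standard 0.9 cross-term
balance.  The scale map is `σ = s·1.2/9` for a patch/filter scale `s`
in pixels (the 9-pixel base filter corresponds to σ = 1.2); both
feature families share this map so one scale vector means the same
thing in each branch.

Descriptors are upright by default: a square patch of side `s` centred
on a grid point is divided 4×4; each subregion is sampled on a 5×5
lattice; Haar responses (dx, dy) at each sample are weighted by a
Gaussian of width 3.3σ centred on the patch and pooled into
(Σdx, Σdy, Σ|dx|, Σ|dy|) per subregion — 64 values, L2-normalized.
The Haar support side is `2·round(1.5σ)` — a little wider than the
classic 2σ — because dense-grid extraction keeps every location,
including weakly structured ones that interest-point detectors would
discard, and the wider support averages more pixels per response,
stabilizing those descriptors on noisy inputs.  A descriptor whose raw
norm is below 1e−9 (a constant patch up to float cancellation) is
defined as the zero vector with strength 0.

The descriptor `strength` is the variance of the 64 raw values before
normalization; it drives the redundant-feature selection downstream.
A moving-window pooling of detector responses is deliberately not
applied: on a dense grid every location is kept, so there is nothing
for a maxima/mean window to select.

## Nonlinear-family descriptors

The luminance evolves under `∂L/∂t = div(c·∇L)`.  The conductivity
defaults to Perona–Malik g2, `c = 1/(1 + |∇L|²/k²)`, with exponential
(g1) and Weickert (g3) variants behind configuration.  The contrast
parameter k is the 70th percentile of the gradient-magnitude histogram
of a σ = 1 smoothed copy of the source image, floored at 1e−3 for
degenerate (constant) inputs; gradients for the conductivity are
likewise measured on a σ = 1 smoothed copy of the current level.

Each configured scale `s` maps to `σ = s·1.2/9` and to the evolution
time `t = σ²/2` — the time at which *linear* diffusion reaches that σ —
so the nonlinear levels are directly comparable to the Gaussian branch.
Levels are reached by semi-implicit AOS steps:

    L_new = ½ [(I − 2τ A_rows(c))⁻¹ + (I − 2τ A_cols(c))⁻¹] L

with half-point conductivities, zero-flux (Neumann) boundaries, and a
vectorized Thomas solve per row/column.  The scheme is unconditionally
stable and conserves the image mean exactly (the operator has zero
column sums).  One AOS step per inter-level gap is the default
(`aos_substeps` raises accuracy at linear cost); with the conductivity
forced constant the evolution reproduces a Gaussian blur of
`σ = √(2t)` to within 0.02 L∞ at 25 substeps, which bounds the
splitting error.  Note the matching analytic reference uses
half-sample-symmetric reflection, the boundary rule equivalent to
zero-flux.

Descriptors pool first derivatives (np.gradient, bilinearly sampled at
the same fractional lattice as the Gaussian branch) into the shared
4×4 × 4-statistic layout.  Default orientation is upright to match the
Gaussian branch; `assigned` mode rotates the sampling frame by the
prevalent gradient orientation of a disc of radius s/2 and projects the
derivative pair onto the rotated axes, giving approximate rotation
invariance (cosine similarity > 0.9 under a 90° rotation in the test
fixture).

## Vocabulary and encoding

Selection is global over the pooled *training* descriptors per family:
rank by strength descending, keep the top 80% (ceil), ties broken by
(image id, row, col, scale) so the selection is deterministic.
Vocabularies are k-means with k = 400, k-means++ initialization seeded
explicitly, Lloyd iterations, tolerance 1e−4, at most 300 iterations
(scikit-learn's implementation; an exhaustive-partition oracle checks
it on a toy set).  Test images are encoded against the frozen
vocabularies — the vocabulary never sees test data.

Encoding assigns each descriptor to its nearest centroid (Euclidean,
ties to the lowest index) and L1-normalizes the 400 counts so images
with different descriptor counts are comparable; L2 and raw-count modes
exist behind configuration.  The hybrid vector is the Gaussian block
followed by the nonlinear block (800 values).

## Classification

The default classifier is a linear-kernel SVM with C = 1 on
standardized features (train-set mean/sd applied inside the model) in a
one-vs-one multiclass decomposition.  The trained model stores the dual
representation — support vectors, dual coefficients β, pairwise biases
b₁, kernel id and parameters — and prediction evaluates every pairwise
hyperplane `y(x) = Σ β K(x, xₐ) + b₁` from those stored fields alone,
then majority-votes with ties resolved to the lowest class index.  The
two-class decision function is oriented positive → second class (the
fitting library's binary convention); pairwise multiclass decisions are
oriented the other way, and the tests pin both orientations against the
library's own predictions.  RBF and polynomial kernels and a registry
of alternative classifiers (k-NN, decision tree, naive Bayes,
random-forest ensemble, MLP) sit behind the same train/predict
contract.

Evaluation reports the confusion matrix (rows true, columns predicted),
accuracy = trace/total, and per-class TPR = diagonal/row-sum.

## Phantom generator

Phantoms are 96×96 ellipses ("brain") on a dark background with smooth
internal texture and gentle radial shading.  Class signatures:

| class | signature |
| --- | --- |
| `glioma_like` | 3–5 overlapping elliptical lobes, rough internal texture (±0.16) |
| `meningioma_like` | one smooth disc (radius 0.16–0.20 of the half-frame) at the brain periphery |
| `pituitary_like` | one small sharp blob (radius 0.08–0.11) near the centre |
| `no_tumor` | brain texture only |

All lesion classes draw their intensity from one overlapping band
(0.68–0.85 against a 0.42 brain base), so mean intensity cannot
identify the class; the information is in geometry, edge sharpness and
texture — the quantities local descriptors measure.  Every image gets
seeded rotation jitter (±15°), scale jitter (0.9–1.1), and additive
Gaussian noise (σ = 0.02), chosen to exercise the robustness properties
without destroying separability.  Per-image seeds derive
deterministically from the master seed, so datasets are bit-identical
across reruns.

What the phantoms do **not** emulate: tissue-contrast physics, partial
voluming, bias fields, anatomical variability, or the class imbalance
and acquisition heterogeneity of clinical collections.  Passing the
phantom-based suite demonstrates that the pipeline's machinery is
correct and that hybrid features add value over either family on
geometry/texture-coded classes; it does not certify clinical
performance.

## Problem sizes and determinism

The end-to-end evaluation uses 40 images per class (160 total, 128
train / 32 test) at 96×96, giving 73 728 pooled training descriptors
per family — enough for stable k = 400 vocabularies while a full run
stays around a minute on one core.  On that pinned dataset (seed 7)
the hybrid reaches 0.9375 held-out accuracy versus 0.9062 (Gaussian
family) and 0.9375 (nonlinear family), and a 1-NN classifier on raw
8×-downsampled pixels reaches only ~0.59, showing the classes are not
trivially separable.  All randomness flows through three named seeds
(data, split, k-means); refitting with the same seeds reproduces
features, confusion matrix and artifacts exactly.

## Known limitations

* The Gaussian branch computes box filters on the raw image; very high
  noise levels degrade it faster than the diffusion-smoothed nonlinear
  branch (visible in the single-family accuracies).
* `assigned` orientation estimates a single dominant angle; textures
  with symmetric gradient distributions get an unstable angle.
* Histogram encoding is hard-assignment BoVW; soft assignment, Fisher
  vectors and VLAD are out of scope.
* Interest-point detection (octave non-maximum suppression) is out of
  scope: the pipeline is dense-grid by design.
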