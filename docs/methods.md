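# Methods

## Problem and model

The package predicts MGMT promoter methylation status (MGMT+ vs MGMT−)
from 2-D grayscale brain-MRI slices. Methylation of the MGMT promoter
silences a DNA-repair gene and predicts response to alkylating
chemotherapy in glioblastoma; the radiogenomic hypothesis is that this
molecular state leaves a measurable imaging phenotype. The classifier
works per slice: a slice is a 64×64 8-bit image, obtained upstream by
12-bit→8-bit full-scale linear conversion and anti-aliased bilinear
resizing, pooled across MRI modalities into two class folders.

Classification is two-stage feature fusion followed by a conventional
classifier:

1. **Rejection filter.** Slices whose pixel-value sum is ≤ T_h are
   discarded (default T_h = 0, i.e. exactly the all-zero slices that
   skull-stripped volumes produce at their extremes). The comparison is
   inclusive (`sum ≤ T_h`); at T_h = 0 with non-negative pixels this is
   indistinguishable from the strict variant. The filter runs per class,
   before any split, and never touches labels.
2. **Latent features.** A compact CNN — three conv blocks
   (64/128/256 filters of 3×3, each followed by ReLU and 2×2 max-pooling,
   batch-norm after block 2, 20% dropout after block 3) and three fully
   connected layers (512/64/2) — is trained to classify the slices.
   The first two FC layers are then read out as features
   ("feature bleeding"): x_latent = [FC1 (512) | FC2 (64)], 576 values.
   FC1/FC2 carry no nonlinearity, so the harvested activations are the raw
   linear outputs; extraction runs in inference mode (dropout off,
   batch-norm on running statistics), making it a pure function of
   (network, image).
3. **Radiomic features.** Three hand-crafted descriptors per slice:
   13 direction-averaged Haralick features from gray-level co-occurrence
   matrices, a 36-value HOG descriptor, and a 59-bin uniform-LBP
   histogram: x_radiomic = 108 values.
4. **Fusion and classification.** The hybrid feature set
   HFS = [FC1|FC2|GLCM|HOG|LBP] has 684 values with a fixed segment map
   (FC1 is 74.85% of it); any sub-hybrid is a segment selection. Features
   are min-max normalized to [0, 1] with statistics fit on the training
   fold only (constant features map to 0; test values are clipped), then
   classified by 1-NN (default) or SVM under stratified 10-fold
   cross-validation; results are reported as mean ± sample standard
   deviation (K−1 denominator) over folds together with the full metric
   suite (A, S_n, S_p, P_r, NPV, F1, MCC, FPR, trapezoidal ROC AUC, all
   computed from exact confusion counts, percent metrics rounded half-up
   to 2 decimals).

## Network and training details

The CNN reproduces a fixed activation chain: 64×64×64 → 32×32×64 →
32×32×128 → 16×16×128 → 14×14×256 → 7×7×256 → 12,544 → 512 → 64 → 2,
with 6,825,922 learnable parameters; construction validates the chain and
fails naming the first offending layer. Conv-3 uses *valid* padding: the
16×16 → 14×14 drop and the FC1 weight shape 512 × 12,544 (= 512 × 7·7·256)
are consistent only with that choice.

The network is implemented directly in NumPy (im2col convolutions over
BLAS matmuls, float32, hand-written backprop). At this input size and
depth that is entirely adequate on one CPU core (the phantom study trains
in under two minutes) and gives exact control over the update rule.
Training uses the classical momentum update

    v ← μ·v − η·(∇L + λ·W),   W ← W + v

with μ = 0.99, η = 10⁻⁴, mini-batches of 16, cross-entropy loss and
L2 regularization λ = 10⁻⁴ applied to weight matrices only. The momentum
value 0.99 is unusually high but is retained deliberately as part of the
published recipe. Defaults: 5 epochs (the operating point at which the
harvested features generalize best; up to 50 supported), Glorot-uniform
initialization, the input layer subtracting the training-set mean image,
batch-norm running statistics updated with momentum 0.9 (an internal
default). All randomness flows from a single integer seed; a fixed seed
reproduces training bit-for-bit.

In full-pipeline cross-validation the network is retrained inside each
fold by default, so no held-out slice influences the features it is
scored with; a global-training mode (train once, tenth of the cost) is
provided for replication and is what the desk-scale study below uses.

## Descriptor conventions

Texture descriptors vary across the literature; the exact conventions
here are:

**GLCM / Haralick.** Gray levels uniformly quantized to N_g = 8 (the
source work does not state its quantization; 8 levels gives dense
co-occurrence statistics on 64×64 slices; configurable 2–256). Offsets at
distance d = 3 in the four directions, (row, col) terms: 0°→(0,d),
45°→(−d,d), 90°→(−d,0), 135°→(−d,−d); pairs leaving the image are
skipped; no symmetric double-counting. Counts are normalized by the total
number of counted pairs (Σp = 1). Logarithms are natural; 0·log 0 = 0.
The 13 features are computed per direction and arithmetically averaged
("directions-averaged features"); averaging the four matrices first is
available as a replication switch. Degenerate cases are pinned: F3 = 0
when a marginal deviation vanishes, F12 = 0 when max(HX, HY) = 0, F13's
radicand clamps at 0. F4 (variance) is computed over the pooled marginal
(p_x + p_y)/2 — the printed formula is ambiguous, and only a
pair-order-symmetric reading keeps the direction-averaged vector
invariant under 90° image rotations, which it should be by symmetry.

**HOG.** Sobel gradients (reflective borders), unsigned orientation over
[0°, 180°), 9 bins with centers at k·20° and circular linear
interpolation (a pure horizontal gradient votes entirely into bin 0),
magnitude-weighted, per 32×32 cell; 2×2-cell blocks at one-cell stride,
each block L2-normalized as T/√(‖T‖² + ε²) with ε = 10⁻⁶. On 64×64 that
is one block of four cells: 36 values. The descriptor is exactly
invariant to intensity shifts and, up to ε, to global intensity scaling.

**LBP.** p = 8 samples on a radius-5 circle, angular origin at the
rightmost point, counter-clockwise, bilinear interpolation at non-integer
coordinates; threshold H(x ≥ 0) against the center (inclusive, so a flat
neighborhood gives the all-ones code), bit k weighted 2^k. Histogram over
the 58 uniform codes (≤ 2 circular transitions, ascending order) plus one
pooled non-uniform bin — p(p−1)+3 = 59 bins — computed over the interior
(border of width r excluded) and normalized to sum 1. The non-rotation-
invariant uniform code set is used because only it yields the published
bin counts {45, 59, …, 135} for p = 7…12. The codes depend only on signs
of intensity differences, so the descriptor is invariant to monotone
intensity transforms; with interpolated sampling this is exact for affine
maps and for arbitrary strictly monotone maps whenever the sample points
are grid-aligned, which is how the property is tested.

**k-NN.** Default k = 1 with the standard Euclidean distance. The printed
distance-table variants (Euclidean with 1/k inside the radical; a
"chi-square" row that is actually the Chebyshev formula) are selectable
by name but are not defaults. Weighted voting V(y) = Σ d⁻ᶻ over matching
neighbors is available (z = 2 default); vote ties break toward the
nearest neighbor; a zero-distance neighbor under weighted voting decides
directly. The ROC score is the positive-class vote share. SVM (linear,
RBF, polynomial degree 2–4) is backed by a standard soft-margin solver
with C = 1, RBF scale 1/(n_features·Var), polynomial offset 1; its ROC
score is the signed decision value.

## Synthetic phantoms

The phantom generator provides a fully deterministic two-class dataset
so the complete pipeline is testable without the (multi-hundred-GB) real
mpMRI download. Class 0 is an isotropic Gaussian random field with
correlation length 6 px; class 1 is a 30°-oriented sinusoidal grating
(period 8 px, random phase) plus a rough field (correlation length
1.5 px); both sit on a 120-gray-level pedestal with additive Gaussian
noise (σ = 8) and clip to [1, 255] so no textured slice is ever blank.
A configurable fraction (default 10%) of exactly-zero slices per class
exercises the rejection filter. The defaults (200 images per class) were
fixed once as the desk-scale study conditions. Each descriptor family is
individually informative by design — orientation for HOG, correlation
length for GLCM, micro-pattern density for LBP — so "the fusion at least
matches its parts" is a meaningful, testable property.

What the phantoms do *not* emulate: brain anatomy, modality-specific MRI
contrast, intra-class heterogeneity of real tumors, scanner effects, or
label noise. Passing the phantom study therefore demonstrates that the
pipeline is implemented correctly and that fusion behaves as designed on
separable texture classes; it does not certify the classification
accuracies reported on the real dataset, which require the full download
and are out of scope here.

## Numerical choices and edge cases

* Percent metrics round half-up to 2 decimals; zero denominators yield a
  defined 0 with the affected metric flagged rather than NaN.
* ROC AUC is computed via mid-ranks (equivalent to trapezoidal
  integration; ties count ½).
* Stratified folds: seeded within-class shuffle, round-robin assignment;
  per-class fold counts differ by ≤ 1; a class smaller than K is an
  error. The secondary 80:20 split mode rounds the per-class training
  count half-up.
* 12-bit→8-bit conversion is the fixed full-scale map value·255/4095
  with round-half-up — not per-image min–max — so intensities remain
  comparable across slices.
* Unreadable files during rejection are logged and counted as
  rejected-with-error, preserving the count identity
  original = kept + rejected.
* Softmax is max-shifted; a zero predicted probability at the target
  class is clamped at 10⁻¹² and logged.
* Mahalanobis k-NN estimates covariance on the training fold with
  diagonal loading 10⁻⁶.

## Study sizes

The bundled study uses 200 slices per class (360 after rejection),
5 training epochs, and one globally trained network before 10-fold
cross-validation — sizes chosen so the whole study, including every
per-segment cross-validation, completes in a few minutes on a single CPU
core while still exercising each stage at meaningful scale. The published
full-scale experiments (≈350k slices, GPU training) are reproducible
through the same pipeline entry points given the real dataset directory.

## Known limitations

* Per-slice classification ignores patient-level correlation; slices of
  one patient can land in different folds on real data unless the caller
  groups them (the published protocol pools slices the same way).
* The rejection mechanism only detects blank slices; "redundant" slices
  with content are not filtered.
* Momentum 0.99 with lr 10⁻⁴ converges but can oscillate on tiny
  training sets; the loss-decrease property is therefore stated across
  seeds (≥ 90% of runs), not per run.
* HOG at non-default geometries with more than one block is implemented
  but not exercised by the published configuration.
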