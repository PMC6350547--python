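# Methods

## Problem and model

`pollenspect` classifies planar thyroid-scintigraphy (SPECT) images into four
diagnostic categories — Graves' disease, Hashimoto disease, subacute
thyroiditis, normal — with a convolutional network whose two distinctive
ingredients are:

1. **Weighted dense connectivity.** In a dense block, layer *l* receives the
   concatenation of all earlier feature maps. Here each incoming map carries a
   trainable scalar weight:

       y_l = F_l(k_{l,0}·x_0, k_{l,1}·x_1, …, k_{l,l−1}·x_{l−1}; W_l)

   with x_0 the block input and x_i (i ≥ 1) the output of layer i. A block of
   n features therefore holds n(n−1)/2 skip weights. All k start at exactly 1,
   so the initial network coincides with the standard unweighted dense block;
   training then learns how useful each feature map is for the classification.
   Between blocks, the usual average-pooling downsampling is replaced by a
   3×3 convolution with dilation 2 and stride 2 (padding 2), which halves
   even spatial dimensions like the pooling it replaces while enlarging the
   receptive field; a `pool` mode is retained for reference comparisons.

2. **Per-minibatch learning-rate search.** Plain SGD commits
   w ← w − l·∇w without checking that the step actually lowered the current
   minibatch's loss. Here, after the gradient ∇w of the minibatch loss C is
   computed once, the scalar learning rate l is optimized by the flower
   pollination algorithm (FPA) with fitness f(l) = C(w − l·∇w), evaluated by
   one extra forward pass per candidate (no extra backward). FPA maintains m
   candidate rates on [L_min, L_max]; per iteration each candidate moves
   globally toward the best (a Lévy-flight step, l ← l + γ·L·(l_best − l),
   L ~ Lévy(1.5) via Mantegna's algorithm) with probability P_C, or locally
   (l ← l + ε·(l_1 − l_2), ε ~ U[0,1]) otherwise; candidates are clamped to
   the bounds and accepted greedily. The incumbent rate — the rate committed
   at the previous step — is seeded into the population, which makes the
   committed step provably no worse than fixed-rate SGD on every minibatch.

Training uses soft-target cross entropy (the output head applies softmax;
the loss consumes logits), dropout on the classifier head, batch
normalization throughout, early stopping on a stratified validation split
carved from the training set, and restores the best-validation parameters.

### Layer-composite ordering

Each dense layer's transform is **conv → batch-norm → ReLU**. The order is
forced by the skip weights: per-channel batch normalization satisfies
BN(k·x) = BN(x) for every k > 0, so a norm-first composite would cancel the
weighted concatenation exactly (up to the ε in the variance) and the skip
weights could never train. With the convolution first, the weights genuinely
modulate each feature map's contribution; empirically they move by O(10⁻²)
within a few hundred SGD steps, versus O(10⁻⁵) (the ε leak) in a norm-first
variant.

### Fitness determinism

During one FPA search the fitness must be a pure function of the learning
rate, so trial losses are evaluated with dropout disabled and batch-norm
batch statistics frozen (no running-average updates, parameters restored
bit-identically after each probe). The gradient itself is computed in full
training mode. The committed step's recorded `loss_after` is the same
deterministic map, which is what the non-worsening guarantee is stated in.

## Data augmentation

Mixup forms virtual samples X′ = αX_i + (1−α)X_j, Y′ = αY_i + (1−α)Y_j with
α ~ U[0.5, 1] drawn per sample; X_i comes from the class being topped up,
X_j from the whole pool (X_j ≠ X_i). Because α ≥ 0.5, X_i dominates and the
mixed sample is counted toward X_i's class; at α = 0.5 exactly, ties break
toward X_i. Every class is raised to `target_per_class` (default 2000:
starting from the emulated cohort sizes 780/438/810/860 the smallest class
gains 1562 virtual samples), then each class group is randomly partitioned
into 1400 train / 600 test. Augment-then-split is the default ordering; a
`split_first` flag partitions the originals first and augments each side
from its own pool only, for leakage-free evaluation. Undefined behaviour is
rejected early: a class with zero originals cannot be augmented.

## Synthetic data generator

The generator emulates planar thyroid scintigrams as parametric "butterfly"
patterns: two mirrored elliptical lobes plus an isthmus on a dark background,
with additive Gaussian pixel noise (σ = 0.03) and all geometry/intensity
parameters drawn per image from one seeded generator. Class signatures follow
the clinical appearance of each condition:

| class     | gland size      | uptake level | texture               |
|-----------|-----------------|--------------|-----------------------|
| normal    | 1.0×            | 0.50–0.60    | mild heterogeneity    |
| graves    | 1.30–1.50×      | 0.82–0.92    | uniform               |
| hashimoto | 1.0×            | 0.45–0.55    | strong patchiness (±0.2–0.3, smoothed noise) |
| subacute  | 0.85–1.0×       | 0.12–0.20    | uniform, suppressed   |

Generation is a pure function of (class_counts, image_size, seed). Default
image size is 255 to match clinical practice; tests and the desk-scale runs
use 32. What the generator does **not** emulate: tomographic reconstruction
artifacts, attenuation, collimator blur, patient anatomy variation beyond
ellipse jitter, or any overlap between categories' uptake distributions.
Passing tests therefore demonstrate that the pipeline's mechanics (balancing,
training, search, evaluation) work on learnable image data — they say nothing
about diagnostic accuracy on clinical scans, whose class appearance is far
less separable.

## Evaluation

The confusion matrix uses the column-=-actual convention (entry (r, c) counts
actual class c predicted as r), so column sums are the per-class cohort
sizes. Per class, one-vs-rest counts give recall, precision, accuracy,
specificity and F1 = 2TP/(2TP+FP+FN). A metric with zero denominator is
reported as null — never 0 or 1 — and excluded from macro averages (the
number of contributing classes is reported alongside). "Average precision"
curves are macro-averaged one-vs-rest precision per epoch. Report tables are
percentages rounded half-even to two decimals.

## Defaults and tunables

| parameter | default | why |
|---|---|---|
| α range | [0.5, 1] uniform | dominant-component mixing; per-sample draw |
| target / train / test per class | 2000 / 1400 / 600 | balanced cohort construction |
| minibatch size | 5 | small batches suit per-batch rate search |
| FPA γ | 0.1 | scaling factor of the Lévy move |
| Lévy exponent | 1.5 | heavy-tailed exploration |
| FPA m, N, P_C | 10, 10, 0.8 | canonical FPA settings; P_C from the original FPA literature |
| learning-rate bounds | [10⁻⁴, 0.5] | wide enough that clamping is rarely active |
| FPA initial population | uniform on the bounds | the canonical bounded initialization |
| validation fraction | 0.1, per-class stratified | early stopping needs a held-out signal |
| dropout | 0.2, classifier head only | light regularization for desk-scale nets |
| architecture presets | tiny (2 blocks × 3 features, growth 8), small (3 × 4, growth 12, the desk-scale default), full (4 blocks mirroring DenseNet121's 6/12/24/16 conv layers, input 255) | graded problem sizes |

Out-of-bounds FPA candidates are clamped, not resampled. Non-finite fitness
values reject the candidate with a warning; an all-non-finite population is
an error. Plain SGD per w ← w − l·∇w (no momentum or weight decay). The FPA
search is re-run from a fresh population each minibatch, seeded with the
incumbent; `fpa_every_k_steps` can thin the search or disable it (`None`),
in which case the loop is exactly fixed-rate SGD.

## Numerical engine

The network runs on a compact float64 reverse-mode autodiff engine written
for this package (im2col convolution with stride/padding/dilation, batch
norm with exact batch-moment backward, channel concatenation, scalar
feature-map scaling, pooling, affine head, soft-target cross entropy).
Gradients are verified against central differences in the test suite, and
the assembled network at unit skip weights is verified to machine precision
against an independently coded standard DenseNet forward pass
(`pollenspect.reference`, built on `scipy.signal.correlate2d`).

A pretrained-weight loading hook (`load_pretrained`) copies any named tensor
whose name and shape match and reports what was loaded vs skipped; skip
weights and shape-mismatched tensors keep their initialization. This is the
package's answer to how a standard DenseNet checkpoint remains usable after
the architectural changes: matching is structural, not positional.

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` run the pipeline at desk scale —
32×32 images, the `small` preset, 4×200 training images (from 150 originals
per class mixup-balanced to 250 and split 200/50), batch 5, two epochs, FPA
with m = 5, N = 3 on every minibatch — sizes chosen so the full suite runs on
one CPU core in minutes while still exercising every mechanism end to end.
Dataset-construction counts are checked at the full cohort scale
(780/438/810/860 → 2000 per class → 1400/600). The 255×255,
DenseNet121-scale configuration is available through the `full` preset and
the YAML config but is not exercised by the shipped tests.

## Known limitations

* Skip weights are one scalar per connection, not per channel; a per-channel
  variant would be a natural extension.
* The FPA fitness reuses the minibatch gradient, so the search optimizes a
  one-dimensional slice of the loss; curvature effects between steps are
  ignored (as in any line-search-flavoured SGD).
* The synthetic classes are deliberately well separated; reported precisions
  on them are an upper bound of mechanism health, not clinical performance.
* Training is single-process CPU float64; the engine favours numerical
  transparency over speed and does not target GPU-scale workloads.
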