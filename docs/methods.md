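# Methods

`texfuse` implements a hybrid recognition pipeline for B-mode ultrasound
patches: handcrafted texture analysis and CNN activation features are fused
at the classifier level to separate hepatocellular carcinoma (HCC) tissue
from the cirrhotic parenchyma (PAR) it evolves on. This note records the
models, the defaults and the design decisions that were genuinely open.

## Patch extraction

Tumors are delineated as polygons in VGG Image Annotator (VIA) JSON. A
square window (56 px by default, 50 px configurable) slides over the image
at a configurable stride (default: the window size, i.e. non-overlapping;
the sampling stride is not dictated by the annotation format and is a free
parameter). A window becomes an HCC patch when the fraction of its area
outside the tumor region is below `max_foreign_fraction` (default 0.001,
i.e. 0.1 %), a PAR patch when the fraction inside is below the same bound,
and is discarded otherwise. Area fractions use pixel-center membership with
polygon boundaries counting as inside; at 50–56 px windows this differs from
exact polygon clipping by less than one pixel row, and it makes the rule
exactly checkable against a brute-force oracle. Augmentation (rotation,
translations, scaling, horizontal flip) keeps the original patch, records
the transform, and fills borders by reflection. Splits are stratified
(75/8/17 train/val/test for CNN training, 75/25 for conventional
classifiers, apportioned by largest remainder so the whole-dataset fractions
are met exactly) and group every augmented copy with its source patch, so no
augmented view of a test patch can leak into training — the grouping policy
is a deliberate conservative choice.

## Synthetic speckle benchmark

Real clinical ultrasound data cannot ship with the package, so the test bed
is a fully-developed-speckle simulator. Two independent zero-mean Gaussian
fields with isotropic Gaussian autocorrelation (length `correlation_length_px`,
achieved by smoothing white noise with a Gaussian kernel of
sigma = length/sqrt(2) and renormalizing by the exact discrete kernel norm)
are combined as an envelope; with no blobs the envelope marginal is exactly
Rayleigh with scale `base_scale`, which the tests verify against the
closed-form mean sqrt(pi/2)·scale and a Kolmogorov–Smirnov check.
Heterogeneity is added by multiplying the envelope with 1 + c·b(x), where b
is a normalized sum of Gaussian bumps (count and contrast per class).
Patches are min–max rescaled to 8 bits, matching B-mode display convention
and pinning the texture operators to a fixed alphabet.

Class defaults — HCC: correlation length 2.5 px, 6 blobs, contrast 0.45;
PAR: 1.2 px, 1 blob, contrast 0.15 — emulate the coarser, more
heterogeneous, hyperechogenic appearance of advanced tumors against finer,
more homogeneous parenchyma. They are *benchmark conditions*, not
quantitative claims about liver echotexture: the generator has no acoustic
model (no point-spread function, attenuation, or depth dependence), its
blobs are smooth and isotropic, and the two classes differ far more cleanly
than clinical data do. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its ordering properties hold on a
separable two-class texture problem; they say nothing about clinical
accuracy.

## Texture battery

All features are computed on the median-filtered patch (3×3 by default).
The battery (559 features at defaults) comprises:

- **First-order**: mean, min, max.
- **Second-order GLCM** (256 gray levels, distance 1, signed directions 0°,
  45°, 90°, 135°, unsymmetrized) with Haralick statistics: homogeneity,
  energy, entropy, correlation, contrast, variance. Direction-averaged
  shorthands (`GLCM_contrast`, …) are also emitted.
- **Third-order GLCM** over collinear triples (current pixel central;
  directions θ, θ+180°) and right-angle triples (current pixel at the 90°
  corner; θ, θ+90°). Order-3 contrast and homogeneity use the tuple spread
  max−min, which reduces to |a₁−a₂| at order 2; order-3 correlation is the
  mean of the three pairwise correlations of the 2-D marginals. These
  generalizations were chosen because no canonical third-order Haralick
  formulas exist; the reduction property anchors them to the standard
  definitions.
- **TMCM** (textural microstructure co-occurrence): each pixel's 3×3
  neighborhood vector is clustered with k-means (k ∈ {250, 500}, capped at
  the number of distinct vectors), and the co-occurrence tensors are built
  over cluster labels. Clustering neighborhood vectors rather than bare gray
  levels is what makes k = 500 meaningful beyond the 256-level alphabet.
  k-means is seeded Lloyd iteration initialized from k distinct observed
  vectors; for speed it fits on a seeded subsample (default 2048 vectors,
  10 iterations) and assigns all pixels. Counts are stored sparsely
  (coordinate lists), so 256³-cell third-order tensors cost only the number
  of observed tuples.
- **Edge features**: Sobel gradients; edge pixels are those above the 0.75
  magnitude quantile (a quantile, not an absolute threshold, so the features
  survive per-patch intensity rescaling); edge frequency, mean magnitude
  over edge pixels, and orientation variability = circular variance of
  doubled orientations (folding the 180° ambiguity). The circular-variance
  reading of "orientation variability" is an interpretation and is isolated
  in one operator.
- **Laws microstructures**: the five symmetric 5×5 kernels (level, edge,
  spot, wave, ripple) as outer products of the classic 1-D kernels; density
  = mean absolute response, frequency = fraction of pixels above that mean.
- **Multiresolution**: Haar wavelet applied recursively twice on the
  approximation band; Shannon entropy of the normalized squared coefficients
  of the six detail bands and the final approximation. All sub-band
  entropies are emitted so any subset can be selected downstream. The Hurst
  index is half the log-log slope of the isotropic variogram over lags 1–8
  (validated against spectral-synthesis fractional Brownian surfaces); the
  autocorrelation index is the circular normalized autocorrelation at lag
  (1, 1).
- **LBP** for (radius, neighbors) ∈ {(1, 8), (2, 16), (3, 24)}: circular
  neighbors by bilinear interpolation, bit set iff sample − center > 0
  (strictly, with an epsilon guarding interpolation round-off so flat
  regions give code 0), full 2^N histogram rebinned to 100 equal-width bins
  and normalized. Strict thresholding makes the histograms exactly invariant
  to affine gray maps; under nonlinear monotone maps the invariance is
  approximate because interpolation averages before comparing.

Degenerate inputs return 0 for correlation-type quantities (flat patches,
zero marginal variance) so feature vectors stay finite.

## Deep features

The CNN stack is a self-contained NumPy engine (im2col convolutions over
BLAS, inference-mode batch/layer norm, manual backprop for the small
trainable network). Five backbones are provided with faithful forward
architectures and randomly initialized weights — ResNet101 (tap *pool5*,
2048), InceptionV3 (*avg_pool*, 2048), EfficientNet_b0 (*GlobAvgPool*,
1280), EfficientNet_ASPP (*gapool*, 3×256 = 768 at the default branch
width), ConvNext_base (*adaptiveAvgPool2d*, 1024) — plus `tiny_test_cnn`, a
3-conv-block grayscale network (tap width 64) that supports full
backpropagation and is the workhorse of the desk-scale experiments. Tap
widths are reported from the built graphs; the EfficientNet head width is
the canonical 1280 (a printed value of 1283 in the source material matches
no head arithmetic and is treated as a typo). The ASPP head runs a 1×1
convolution and two 3×3 atrous convolutions (rates 2 and 3, padded to
preserve spatial size) in parallel, depth-concatenates, global-average
pools, and applies dropout 0.5.

Fine-tuning uses SGD with momentum at the study hyperparameters (learning
rate 2·10⁻⁴, momentum 0.9, minibatch 30, 100 epochs, 2 outputs), all
overridable. Full-network training is supported for the tiny CNN; for the
large backbones the 2-way head is trained on frozen tap features (both
modes are exposed because the original training depth is unspecified).
Grayscale patches are replicated to three channels and bilinearly resized
to each backbone's canonical input. Extraction runs in evaluation mode
(dropout inactive) and is deterministic.

## Dimensionality reduction

- **IGA**: information gain H(C) − H(C|A) in bits on equal-frequency
  10-bin discretized features; ranking is descending and selection keeps
  strictly positive gain (the cut-off is a package choice; only the ranking
  itself is canonical).
- **CFS**: merit k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with symmetric-uncertainty
  correlations on the same discretization, searched best-first forward with
  a stale limit of 5 expansions; merits are updated incrementally so each
  expansion costs one new pair correlation per candidate.
- **Intersection** of CFS and IGA subsets, falling back to the first subset
  with a warning when empty.
- **Binary PSO**: canonical inertia/cognitive/social velocity update
  (defaults: swarm 30, 50 iterations, inertia 0.72, c1 = c2 = 1.49, clamp
  ±4), sigmoid transfer, stochastic bit sampling; the fitness is
  0.8·error + 0.2·(selected/total), with error the mean of k-NN (k = 5) and
  diagonal-Gaussian naive-Bayes error rates on a seeded stratified 70/30
  inner holdout. The all-ones mask is seeded into the swarm so the returned
  best never loses to selecting everything; the all-zero mask is defined as
  fitness 1. The swarm mechanics constants are package defaults, as is the
  inner-holdout protocol.
- **KPCA**: features standardized with training statistics; linear,
  3rd-degree polynomial (gamma = 1/d, offset 1) or Gaussian kernel
  (bandwidth = median pairwise distance of the fitted data unless set);
  double-centered Gram matrix, leading eigenvectors scaled by inverse root
  eigenvalues, components ordered by descending eigenvalue, truncated with a
  warning when fewer positive eigenvalues exist than requested (a centered
  Gram of n rows has rank at most n − 1, so 500 components need at least
  501 training rows).

## Fusion and evaluation

Six schemes combine the texture matrix and a deep matrix: plain
concatenation; selection within each source then concatenation; concatenation
then selection; concatenation then PSO selection; 300 KPCA components per
source then concatenation (600 columns); concatenation then 500 KPCA
components. Every data-dependent transform is fitted on training rows only
(a leakage test mutates held-out rows and asserts the fitted transform is
unchanged). Evaluation standardizes features and trains an SVM with a
3rd-degree polynomial kernel, a 100-tree random forest, and AdaBoost with
entropy-based decision trees (100 rounds by default; the base learner is a
pre-pruned top-down information-gain tree standing in for C4.5 — exact J48
semantics are not reproduced). Metrics are accuracy, sensitivity
(true-positive rate of HCC), specificity and AUC on the 0–100 scale, HCC
positive; AUC uses decision scores for the SVM and class probabilities for
the ensembles. The comparison statistic between two metric quadruples is the
mean of the four differences; both sign conventions are exposed (the usual
tabulation prints the opposite sign, other minus current) and the magnitude
is invariant.

## Imagistic model

The model document collects: the relevance ranking of textural features —
the mean of each feature's information-gain score across its fused
combinations with every backbone; per-feature class-conditional mean,
standard deviation and a 20-bin histogram probability distribution (the
histogram form is a package choice); the full textural×deep Pearson table
with zero-variance columns recorded as undefined rather than coerced to 0
and excluded from extremal summaries; and feature-map images — a vector
reshaped row-major into its maximal square (side = floor(sqrt(length)),
discarding fewer than 2·side+1 trailing values) and min–max rescaled — whose
per-class statistics are computed on the pixelwise class-mean image (one
representative map per class), with per-image statistics retained alongside.

## Problem sizes and numerical choices

The shipped experiments use sizes chosen to keep the whole suite
reproducible on a single core in minutes: the fusion benchmark runs 1000
generated patches per class, one generated dataset, three pipeline seeds
(split, CNN initialization/training, classifier randomness), 5 tiny-CNN
epochs, a reduced PSO budget (swarm 12, 15 iterations, 400-row inner
subsample) and bounded AdaBoost (depth-3 base trees, 40 rounds) — the
study-default classifier settings remain the defaults of
`texfuse.fusion.evaluate`. The acceptance script runs the same pipeline at
300 patches per class with one pipeline seed. Oracle-equivalence checks
(co-occurrence, patch extraction, median filter, Pearson, PCA) are exact;
stochastic checks (planted-feature recovery, Rayleigh statistics, Hurst
recovery, chance-level AUC) state their seed counts and bounds in the tests.

## Known limitations

No pretrained weights are bundled, so deep features come from randomly
initialized or lightly fine-tuned networks; clinical-grade accuracy claims
are out of reach by construction and out of scope. The synthetic benchmark
is nearly separable at the default class gap, so the fusion-scheme ordering
property is a soft consistency check, not a power comparison. Exact Weka
semantics (MDL discretization, J48 pruning, SMO internals) are replaced by
documented equivalents. DICOM ingestion, acoustic simulation, and
decision-level fusion are not implemented.
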