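# Methods

This note documents the models and procedures implemented in `hemotex`,
the defaults and why they were chosen, the numerical conventions, and the
limits of what the phantom-based tests demonstrate.

## Intensity convention and I/O

All computation happens on 2D float grids in [0, 1] (`IntensityImage`),
row-major `(r, c)` with 0-based indexing. DICOM input is converted to
Hounsfield units via rescale slope/intercept and mapped through a CT
window, `clip((HU − (c − w/2)) / w, 0, 1)`; the default is the standard
radiology brain window (center 40 HU, width 80 HU). PNG is divided by its
bit-depth maximum and NIfTI min-max scaled, both assumed pre-windowed.
These are conventions, not reconstructions of any specific scanner
pipeline — the thresholding and texture stages only require a consistent
normalized scale.

## Phantom generator

Each phantom slice is a hard-edged geometric rendering of an axial head
CT: air background 0.0, skull annulus 0.95 (outer radius 0.46·min(M,N),
thickness ≈ 3.5 % of the image side), brain disk 0.35, lesion 0.65,
ventricle 0.20 (drawn only for the intraventricular subtype), plus i.i.d.
Gaussian noise (default σ = 0.02) clipped to [0, 1]. Default size
128 × 128; lesion shapes per subtype:

* **epidural** — intersection of the brain disk with an external circle
  of equal radius, giving a biconvex lens flush to the inner skull;
  penetration depth 0.35·R_brain·scale;
* **subdural** — annular crescent of width ≈ 0.10·R_brain hugging the
  inner skull over an arc drawn uniformly in [90°, 150°];
* **intraparenchymal** — rotated filled ellipse (semi-axis ≈
  0.30·R_brain·scale) kept strictly interior (centre + axes ≤ 0.92·R_brain);
* **intraventricular** — ellipse inside a central ventricle ellipse
  (0.34 × 0.20 ·R_brain);
* **subarachnoid** — a 2–3 px ribbon along r(φ) = R_brain·(0.86 +
  0.05·sin(3φ + phase)) over an arc near the cortical margin.

Positions, orientations, arcs and a ±15 % size jitter are drawn from the
per-sample seed; dataset seeds are `base_seed + index` with samples in
subtype-major order, so any subset regenerates independently. A "scan" is
K consecutive slices (default K = 8) sharing one geometry whose extent
follows a half-sine wax/wane profile (0.55–1.0 of nominal size), giving
the sequence classifier a genuine through-plane axis without 3D rendering.

Noiseless phantoms have exactly two intensity levels inside the brain
ROI, which forces the Otsu split between them and yields Dice = 100 % —
this is the generator's built-in oracle for the segmentation stage.

What the phantom does **not** emulate: partial-volume edges, beam
hardening and streak artifacts, anatomical texture inside the parenchyma,
skull thickness variation, mass effect, or multiple simultaneous bleeds.
Passing the end-to-end tests therefore shows the pipeline machinery is
correct and that shape/contrast information flows through it — not that
the feature set suffices on clinical CT.

## Segmentation

Otsu's method over an l-bin histogram (default l = 256, equal-width bins
on [0, 1], the value 1.0 assigned to the last bin). For each candidate
split t ∈ {0..l−2} the class weights, bin-center means and variances are
computed by direct summation, and t minimizes σ²_w(t) = w_b σ²_b +
w_f σ²_f, ties toward the smallest t. Direct (non-cumulative) summation
is deliberate: splits that pass through empty bins describe identical
partitions and must compare exactly equal, which cumulative-sum rounding
breaks. The equivalent between-class maximization w_b w_f (μ_b − μ_f)² is
used as a cross-check; the within + between = total-variance identity
holds to 1e-10, and index-level agreement is exact up to floating-point
ties below 1e-12.

A `fixed` mode thresholds at a constant t (default 0.5 on the normalized
scale) instead of optimizing; `otsu` is the default. The ROI mask keeps
pixels strictly above the threshold, optionally restricted to a
brain-interior mask (skull-stripped by an intensity gate ≥ 0.9 plus hole
filling), with 8-connected components under `min_object_px` (default 10
in the pipeline, 0 in all oracle tests) removed. A degenerate
single-level histogram falls back to the fixed threshold with a warning;
an empty result mask is a legitimate output, not an error.

## Texture descriptors

**Sobel gradients.** 3 × 3 Sobel–Feldman kernels, borders
edge-replicated, magnitude √(G_i² + G_j²).

**GLTP.** For every interior pixel, each of its 8 neighbors' gradient
magnitudes is coded against the center magnitude G_c: −1 below G_c − t,
+1 above G_c + t, 0 inside the band. The negative and positive bits form
two 8-bit codes (bit 0 at the top-left neighbor, clockwise — an arbitrary
but frozen order), whose 256-bin histograms concatenate into the 512-bin
descriptor. The band threshold is t = 0.05 after dividing the magnitude
field by its image maximum, which makes one default serviceable across
images of different contrast. Additive intensity shifts leave the
descriptor bit-identical (gradients are shift-invariant); contrast
scaling does not (without the rescale), and both properties are tested.
Histograms are normalized by the encoded-pixel count in the pipeline
(`normalize_hist=True`) so crop size does not leak into the features.

**Tamura features.** Coarseness: per-pixel local means over 2^k windows
(k = 0..5, reduced with a warning when the image is too small),
differenced across 2^(k−1)-pixel shifts in both axes; pixels whose
shifted windows would run off the image are excluded per scale (clamped
windows would fake large-scale structure); each pixel keeps the scale
with the largest difference (ties toward the smaller k) and the feature
is the mean of 2^k_best, hence ≥ 1 with equality on constant images.
Contrast: σ/α₄^¼ with α₄ = μ₄/σ⁴, 0 for constant regions; linear in
intensity scaling; equals 0.5 on a half-0/half-1 image (α₄ = 1).
Directionality: edge angles atan2(G_j, G_i) mod π of pixels above a small
gradient floor, quantized into 16 bins; with the single-global-peak
simplification the score is 1 − n_θ · Σ_b H(b)·d(b)², d the wrapped bin
distance to the peak as a fraction of the range, clipped to [0, 1]. A
single tight peak scores ≈ 1, isotropic noise ≈ 0, and the measure is
invariant to 90° rotations. Multi-peak detection is out of scope.

**Fusion.** The image is cropped to the ROI bounding box, expanded to a
square (minimum side 3·B or 16 px, edge-padded when the image runs out);
Tamura triples are computed per block of a B × B partition (default
B = 4) and concatenated with the GLTP histogram of the whole crop:
3·B² + 512 = 560 values, names prefixed `tamura_*`, `gltp_n_*`,
`gltp_p_*` in a fixed documented order. Computing texture on the crop
(not the whole image) keeps the descriptor about the lesion and its
immediate context — for near-skull subtypes the bright skull entering the
bounding box is itself a discriminative cue, as it is for a radiologist.

## Feature selection

**Inf-FS ranking.** Features are nodes of a graph with adjacency
A(i,j) = c·(1 − |ρ_ij|) + (1 − c)·max(s_i, s_j), where ρ is Spearman
correlation (computed as Pearson on ranks so constant features degrade to
0 rather than breaking the shape), s the per-feature standard deviation
rescaled by its maximum, and c = 0.5. The path energy
S = (I − rA)⁻¹ − I = Σ_{l≥1} r^l A^l sums the weight of all walks through
each feature; r = 0.5/ρ_spectral(A) guarantees convergence. Higher energy
means relevant-and-non-redundant: an exactly duplicated feature pair
scores below comparable independent features.

**Genetic algorithm.** Bit-string chromosomes (bit = feature kept,
repaired to ≥ 1 bit), fitness α·γ + (1 − α)·sparsity with α = 0.9. Two
sparsity terms: `normalized` (default) rewards
(n_features − n_selected)/n_features, bounded in [0, 1); `relative`
rewards (n_features − n_selected)/n_selected, unbounded as subsets shrink
(kept for fidelity experiments; it can dominate γ). γ is the accuracy of
a 1-NN surrogate (Gaussian naive Bayes available) on stratified 70/30
hold-outs whose splits are fixed per GA run so all chromosomes are scored
on the same rows; γ averages `n_eval_splits = 3` repeats because a single
150-point hold-out saturates on well-separated data, after which the
sparsity term would strip still-informative features without penalty —
averaging restores the gradient at triple the evaluation cost.

Generational loop: roulette parent selection on min-shifted fitness
(tournament k = 3 available), single-point crossover at 0.80,
elite count 2 (which makes the best-so-far trace non-decreasing by
construction), exactly `generations` iterations (default 100), population
defaulting to n_features capped at 200. Mutation applies, with
probability 0.1 per child, **one Inf-FS-guided bit flip**: the flipped
bit is drawn with weights favoring switching ON high-energy features and
OFF low-energy ones (uniform when no ranking is available; a literal
per-bit mode exists). Guided mutation is how the Inf-FS regularization
enters the search itself, beyond initialization: it gives drift a
direction when fitness is locally flat. Initialization sets bit i with
probability linear in Inf-FS rank (0.8 top to 0.2 bottom), plus one
chromosome forced to the top-half features. After the run, near-duplicate
selected features (|ρ| > 0.95) are pruned keeping the higher energy one.

## Classifier

A bidirectional LSTM implemented directly in NumPy. Per-gate parameters
(W_gh recurrent H×H, W_ga input H×F, bias b_g for g ∈ {i, f, c, o}),
cell update

    i, f, o = σ(W·h_prev + W·a_t + b)       (three sigmoid gates)
    c_t = f ⊙ c_prev + i ⊙ tanh(W_ch h_prev + W_ca a_t + b_c)
    h_t = o ⊙ tanh(c_t)

One cell runs t = 1..T, an independent cell t = T..1; their final hidden
states concatenate (2H) into a dense softmax head. Training is mini-batch
Adam (lr 0.001, β = 0.9/0.999) on cross-entropy with global
gradient-norm clipping at 1.0, batch size 27, full backpropagation
through time, uniform ±1/√H initialization with forget-gate bias 1.
Defaults: H = 64, 100 epochs. Sequences are either a K-slice scan's
per-slice feature vectors (`slices` mode, the default and natural reading
for CT stacks) or a single vector zero-padded and reshaped to
chunk_T × ⌈len/chunk_T⌉ (`chunked` mode for 2D-only data). Runs are
deterministic given the seed under single-threaded BLAS. Models serialize
to a documented JSON schema (shapes + flat arrays).

## Evaluation and pipeline

Classification metrics come from one-vs-rest counts per class:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n,
F1 = Dice = 2TP/(FP+2TP+FN), Jaccard TP/(TP+FP+FN), and MCC with the
standard square-root denominator; all in percent, zero denominators
reported as 0 with a warning. Scalar summaries are unweighted macro means
over the five classes (the averaging rule is otherwise ambiguous for a
multi-class problem); per-class values are always emitted. The same
Dice/Jaccard formulas on pixel counts score segmentation, with two empty
masks scoring 100 by convention.

`run_pipeline` generates (or accepts) a scan dataset, segments and
featurizes every slice, and under a stratified, seeded k-fold plan (k ∈
{3, 5, 8, 10} supported, default 5): standardizes features with
training-fold statistics, runs the GA on per-scan mean features of the
training fold only, trains the Bi-LSTM on the selected per-slice columns,
and predicts the held-out fold. Nothing fitted ever sees test-fold data
(asserted in code and covered by a perturbation test). The default study
is 5 × 60 scans of 8 slices at σ = 0.02 with a 50-chromosome,
30-generation GA and 40 training epochs — at 300 scans and 560 features
this search is ample, and the full run completes in minutes on one CPU.
With these settings the pooled macro accuracy is ≈ 99 % and mean
segmentation Dice ≈ 95 %; the report carries per-fold and pooled metrics,
GA traces, segmentation overlap, the confusion table and the resolved
config, and reruns are byte-identical.

## Degenerate inputs and numerical conventions

Images below 3 × 3 are rejected (Sobel needs a neighborhood); phantom
sizes below 32 px per side are infeasible. Empty ROI masks are errors for
feature extraction (the pipeline falls back to the whole brain mask when
segmentation returns empty); empty chromosomes are repaired by setting
one random bit; single-class training sets are errors. Argmax ties break
toward the lower index everywhere (Otsu split, coarseness scale,
predicted class). Probabilities from the softmax sum to 1 within 1e-9;
gate outputs are strictly inside (0, 1).

## Known limitations

* The phantom's five shapes are linearly well-separated at default
  contrast; reported phantom accuracies are upper bounds of machinery
  correctness, not clinical performance estimates.
* The contrast knob's effect on end-to-end accuracy is a cliff near the
  noise floor (σ = 0.02): contrasts well above it differ only within
  run-to-run sampling noise, so the monotonicity test compares levels
  that straddle the cliff.
* Tamura directionality uses a single global peak; strongly multi-modal
  edge-angle distributions are under-described.
* The GA wrapper inherits 1-NN's sensitivity to feature scaling; the
  pipeline standardizes features first, but library users calling
  `evolve` on raw features should do the same.
* Sequence length is fixed per dataset (no padding/packing of variable-T
  batches).
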