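# Methods

This note records the models implemented in `woundbed`, the parameter
choices made where the procedure admits more than one reasonable
reading, and what the synthetic test bed does and does not establish.

## Segmentation model

The wound bed is segmented on the HSI saturation plane, rescaled to
[0, 255].  Saturation measures how far a color lies from the gray axis;
healthy skin is close to gray while granulation and slough tissue are
strongly chromatic, so a single saturation threshold separates them
well.  For a candidate threshold *t*, pixels with S ≥ *t* form the
object region and the rest the background; each pixel's Gaussian
membership grade exp(−(f − m_r)²/2σ²) expresses how typical it is of its
own region's mean m_r.  The exponential fuzzy divergence between this
membership image and an ideally segmented image (membership 1
everywhere) quantifies residual edge ambiguity; the scan over all 255
candidate thresholds picks the minimizer, breaking ties toward the
smallest threshold so results are deterministic.

Numerical choices:

* **σ = (max − min)/2 of the channel, floored at 1.**  Parameter-free
  and scale-aware; a constant channel is rejected as degenerate rather
  than given an arbitrary threshold.
* The scan quantizes the channel to 8 bits and collapses the per-pixel
  divergence sum onto the 256-bin histogram (membership depends only on
  gray value once the split is fixed).  This is an exact algebraic
  rewrite, not an approximation, and the test suite re-verifies it
  against a per-pixel brute-force scan.
* **Refinement**: morphological closing then opening with a disk of
  radius max(1, round(3·min(H, W)/512)) — radius 3 at roughly
  megapixel scale, shrinking with the image — then hole filling and
  retention of the largest 8-connected component.  A wound photograph is
  assumed to contain one wound; multi-wound images are out of scope.
* **Object = high-saturation side.**  Wound tissue is the chromatic
  side of the threshold in this color model.

A consequence worth stating plainly: necrotic eschar rendered as a
neutral black is *less* saturated than skin, so a saturation threshold
cannot claim it directly.  In mixed wounds the chromatic tissue
dominates the boundary and the refined mask still overlaps the true bed
well; a wound dominated by neutral-dark eschar is outside what this
segmentation method can delineate.

## Feature bank

675 features per region: 15 per channel × 45 channels, ordered
channel-major (`woundbed.color.CHANNEL_IDS` fixes the channel order; a
JSON manifest can be exported for self-describing CSV columns).

* **Color moments** use population (1/N) formulas; skewness and
  kurtosis (non-excess) are defined as 0 for zero-variance regions so
  classifiers never see non-finite values.
* **Shannon entropy**, the **mode** used by local contrast, and the
  **LBP comparisons** operate on a 256-bin quantization of each channel
  over its declared range (documented per channel in the manifest);
  moments and the mean/median local contrasts use raw values.  The
  declared ranges are the analytic output ranges of each transform for
  8-bit sRGB input.
* **Local contrast** (T − A)/(T + A) splits the region at a central
  measure (mean, median, or the histogram mode, smallest bin on ties)
  and is 0 when either side is empty or T + A = 0.
* **Texture**: P = 8R neighbors on a circle of radius R ∈ {1, 2, 3},
  sampled by bilinear interpolation, neighbor p at angle 2πp/P from the
  +x axis.  The rotation-invariant LBP code is the minimum over all P
  circular bit rotations; VAR is the population variance of the
  neighbor ring.  Only pixels whose entire interpolation support lies
  inside the region mask contribute, so background never contaminates
  tissue texture.  Zero-weight interpolation corners are exempt from
  the in-mask requirement — this makes the valid-pixel set (and hence
  the LBP/VAR means) exactly symmetric under 90° image rotations, which
  the test suite checks.

## Feature screening

Classic one-way ANOVA F per column (between-class over within-class
mean square, (k−1, N−k) degrees of freedom), retaining F > 21 by
default — far out in the null F tail for corpus-sized samples, roughly
p < 0.001.  Conventions: F = 0 when both mean squares vanish; F = +∞
(always retained) for a zero-within-variance column with nonzero
between-class variance, since it separates classes perfectly.  No
multiple-testing correction is applied; the screen is a filter, not an
inference.

## Classifiers

Both learners z-score features with training statistics baked into the
model, so raw queries are standardized transparently.

* **Gaussian naive Bayes**: class priors are class frequencies;
  per-class per-feature normal marginals are maximum-likelihood fits
  with variances floored at 1e-9.  Posteriors are computed in the log
  domain and normalized; ties break in the fixed class order
  granulation < slough < necrotic.
* **Kernel SVM**: soft-margin dual SVM with kernels x·y,
  (γ·x·y + 1)^d for d ∈ {2, 3}, and exp(−γ‖x−y‖²); defaults C = 1,
  coef0 = 1, γ = 1/(n_features · var(X)).  Multiclass by one-vs-one
  voting with the same tie-break.  Training is delegated to libsvm via
  scikit-learn; prediction is computed from the stored support vectors
  and dual coefficients so a JSON-serialized model predicts identically
  to a freshly trained one (scikit-learn's inverted binary-decision
  convention is normalized away at fit time).  A small quadratic-program
  solve serves as an independent oracle in the tests.

## Evaluation

Per-class accuracy is the row-normalized diagonal of the confusion
matrix (rows = expert label).  Both macro (mean of per-class) and micro
(pooled) overall accuracy are reported; macro is the headline figure.
Cohen's kappa uses the standard marginal-product chance correction.
Percentages are rounded to 2 decimals, half-even.  The default
evaluation protocol is a stratified 70/30 split with a fixed seed;
resubstitution is available as an explicit option, and reports state
which was used.

## Synthetic wounds

The generator emulates the features of wound photographs that the
pipeline depends on: a near-uniform skin-toned background
(RGB ≈ (225, 190, 160)), an elliptical wound bed partitioned into
contiguous angular sectors of granulation (≈ (180, 40, 50)), slough
(≈ (200, 180, 80)) and necrotic (≈ (30, 25, 25)) tissue, Gaussian color
jitter (σ = 8) and a sinusoidal brightness ripple (amplitude 6) inside
tissue, and image-wide salt-and-pepper impulses (2% by default).
Sector pixel counts match the requested fractions exactly by
construction, and all outputs are bit-reproducible under a fixed seed.

Benchmark suites draw tissue fractions around the composition of the
reference corpus the classifiers are meant to face — granulation/
slough/necrotic roughly 0.29/0.59/0.12 by region count — with the
necrotic share kept within [0.06, 0.14] because of the saturation-
threshold limitation above: the generator models the common mixed wound,
not the eschar-dominated one.  The default benchmark uses ten 128×128
images (≈ 30 labeled regions), a size at which the full pipeline runs
in seconds while every stage (thresholding, morphology, all three LBP
radii) operates far from its boundary conditions.

What the generator does **not** emulate: specular highlights, rulers,
hair and background clutter, uneven illumination, perspective and
camera color response, and the gradual tissue-boundary mixing of real
wounds.  Passing the synthetic benchmark therefore demonstrates that
the pipeline's machinery is correct and well-behaved — not that its
accuracy transfers to clinical photographs, which requires an
expert-labeled corpus.  The synthetic classes are also far better
color-separated than real tissue, which is why held-out accuracy
saturates near 100% there.

## Known limitations

* Single-threshold, single-component segmentation: one wound per image,
  chromatic tissue only (see above).
* The hue channels (HSI/HSV/HSL/LCH) are treated as linear scalars;
  their circular topology is ignored, as is conventional for moment
  features but blurs hues near the wrap point.
* No probability calibration for the SVM, no hyperparameter search, no
  bootstrap intervals on kappa.
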