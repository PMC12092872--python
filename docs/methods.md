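# Methods

`petrad` implements a robustness-first radiomics modeling workflow for
binary risk stratification from PET imaging, exercised end to end on
synthetic data. This note records the models, the defaults and the design
choices, and what the synthetic experiments do and do not demonstrate.

## Cohort definition

The clinical target is the binary risk group derived from the Gleason score
(GS), the sum of two histological grades in 1–5. Grouping: GS ≤ 6 and 3+4
are low risk; 4+3 and any GS ≥ 8 are high risk. The grade order matters at
GS 7 (3+4 is low, 4+3 high); other GS 7 compositions (2+5, 5+2) are not
covered by the rule and raise an error rather than being guessed. GS 8 as
3+5/5+3 is grouped high by the GS ≥ 8 branch but flagged with a warning,
because its prognostic grouping is genuinely debated; 4+4, 4+5, 5+4 and 5+5
are unambiguous. "High" is the positive class in every downstream metric.

## SUV conversion and feature extraction

PET activity (Bq/mL) is converted to body-weight SUV: the injected dose is
decay-corrected to scan start with the tracer half-life (¹⁸F: 109.77 min,
the default), divided by body weight, and voxel activity is divided by the
result. Unit tissue density is assumed, so SUV is dimensionless and a voxel
whose activity equals dose/weight at injection time has SUV 1.

Extraction follows the standard chain: z-score intensity normalization of
the whole volume (scale 1), B-spline resampling to 2×2×2 mm (mask:
nearest-neighbor), image filtering, fixed-bin-width discretization (width
0.25) per derived image, feature computation. Derived images are the
original image, ten Laplacian-of-Gaussian scales (σ = 0.5–5.0 mm in steps
of 0.5, scale-normalized by σ²) and the eight sub-bands of a single-level
undecimated coif1 wavelet decomposition (low/high-pass per axis, mirror
boundary). Feature classes and counts per image: 18 first-order, 24 GLCM,
16 GLRLM, 16 GLSZM, 5 NGTDM, 14 GLDM (= 93), plus 14 shape features
computed once from the resampled mask. The profile therefore emits
107 + 10·93 + 8·93 = 1781 named features, 107 from the original image,
930 from LoG scales and 744 from wavelet bands.

Texture conventions (all 3-D): GLCM and GLRLM merge the 13 unique voxel
directions into a single symmetric matrix before feature computation;
GLSZM zones and GLDM dependences use 26-connectivity; GLDM dependence is
1 + the number of equal-level neighbors (tolerance α = 0), so every voxel
contributes. Degenerate inputs return guard values instead of NaN: a
single-gray-level VOI has GLCM correlation 1 and MCC 1 (perfectly
predictable neighbors), zero skewness/kurtosis, and NGTDM coarseness is
capped at 10⁶ when no gray-tone differences exist. Mesh volume and surface
area come from a marching-cubes surface of the padded mask; axis lengths
from a PCA of voxel-center coordinates (length 4√λ).

Feature names carry image type, class and base
(`wavelet-LHH_firstorder_Skewness`); the parser also accepts the fully
hyphenated print dialect, including en-dashes and the `first-order`
spelling, and always emits the underscore canonical form.

## Preliminary analysis

The loop runs `reps` repetitions (default 30). Per repetition:

1. **Stratified 80/20 split.** Per-class test counts are the
   largest-remainder apportionment of round(0.2·n), making test-set class
   composition deterministic (143 patients at 72/71 → always 15 + 14 = 29).
2. **Standardization** is fit on the training rows only and applied to the
   test rows (prevents leakage; the choice was open and is ours).
3. **LASSO selection**: L1-penalized logistic regression on the
   standardized training split. The penalty is chosen by internal
   stratified 5-fold cross-validation of the deviance over a 20-point grid
   spanning three decades above the null-model bound, with the one-standard-
   error rule by default (`'min'` available). Empty selections are legal:
   the repetition is logged with an empty subset and its models skipped,
   metrics recorded as missing.
4. **Tuning**: each of the six families (DA, SVM, KNN, NN, RF, AdaBoost) is
   tuned by Bayesian optimization of the cross-validated misclassification
   error over the same five folds — the fold assignment is a function of the
   master seed and the repetition index only, never of the family. The
   optimizer is a Matern-5/2 Gaussian-process surrogate with expected-
   improvement acquisition over encoded mixed spaces (one-hot categoricals,
   log-scaled positive reals); default budget 30 evaluations (15 in the
   scaled-down test runs). Search spaces: DA kernel ∈ {linear, diaglinear,
   pseudolinear, quadratic, diagquadratic} with γ, δ ∈ [0, 1]; SVM C
   log-uniform on [10⁻³, 10³] with kernel ∈ {gaussian, linear, polynomial}
   and log-uniform kernel scale; KNN k ∈ [1, 30]; NN hidden size ∈ [1, 32]
   with log-uniform L2; RF trees ∈ [50, 300], depth ∈ [2, 12]; AdaBoost
   trees ∈ [50, 300], log-uniform learning rate.
5. **Testing**: tuned models are refit on the full training split and the
   six metrics computed on the held-out rows.

The per-feature **selection frequency** is 100·n/reps, where n counts the
repetitions selecting the feature; values live on the lattice
{0, 100/reps, …, 100}. Family metrics are averaged over repetitions
(missing cells excluded pairwise) and the candidate set is every family
that tops at least one averaged metric.

## Feature subsets

Eleven threshold subsets keep features with frequency ≥ t for
t ∈ {90, 80, 70, 60, 50, 40, 30, 20, 10, 5, 0}; `features0` keeps every
ever-selected feature. The `finetuning` subset keeps mid-band features
(frequency in [30, 70): lower bound included, upper excluded) whose
repetition-averaged absolute Pearson correlation against the `features70`
members stays below 0.3. The per-repetition correlation is computed on
that repetition's training rows and aggregated over reference members by
the maximum (a candidate redundant with *any* stable feature is redundant;
`mean` is available, since a single printed scalar per candidate cannot
disambiguate the aggregation). Absolute values are used so anticorrelation
also counts as redundancy. `features7030r` is the union of `features70`
and `finetuning`; the band construction makes them disjoint, so sizes add.

## The ensemble

Five members: three discriminant-analysis classifiers with the tuned
(kernel, γ, δ) triples (linear 0.3354/0.2081, diaglinear 0.4298/0.1525,
pseudolinear 0.3722/0.2536), one gaussian-kernel SVM with box constraint
984.2237 (posteriors by sigmoid calibration on training folds; kernel scale
data-driven by default), and one sigmoid network whose single fully
connected layer has size 1 (He-initialized weights, zero biases,
cross-entropy loss, deterministic L-BFGS training). DA semantics: γ shrinks
the pooled covariance toward its diagonal (γ=0 none, γ=1 diagonal); δ
zeroes linear-discriminant coefficients below it in magnitude;
`diaglinear` forces a diagonal covariance and `pseudolinear` inverts via
pseudoinverse. All members are fit on identically standardized features.

The ensemble label is the majority vote of member labels (odd member
count: no tie is reachable; the documented fallback for even ensembles is
score ≥ 0.5 → high). The ensemble score is the weighted posterior
Σwᵢpᵢ/Σwᵢ with wᵢ the member's 5-fold cross-validated AUC on the training
split — using a test AUC as the weight would leak test information, so the
validation flavor is the default (`weight_source="fixed"` degrades to a
plain mean). Scores are invariant to positive weight rescaling; labels
ignore weights entirely. Subset evaluation reuses the preliminary split
plan verbatim (checksum-verifiable) so all models and subsets are measured
on identical test partitions.

## Statistics

AUC is the Mann-Whitney concordance probability with ties counted ½
(exactly the O(n²) pairwise count). Sensitivity/specificity/precision/F1
follow the usual confusion-matrix definitions with "high" positive; zero
predicted positives make precision and F1 undefined (NaN + warning), and
undefined cells are excluded pairwise from averages. Repetition-level
means carry two-sided 95% Student-t intervals (df = n−1) by default; a
percentile-bootstrap option exists because printed asymmetric intervals in
this literature often suggest resampling flavors. Subset comparison uses
the Friedman rank test (midranks, tie-corrected statistic — verified
identical to an independent implementation on tie-free data) followed by
pairwise rank-mean z-tests, z = (R̄ᵢ−R̄ⱼ)/√(k(k+1)/6n), corrected with
Dunn–Šidák p′ = 1−(1−p)^m over the m = k(k−1)/2 pairs; significance at
two-sided 0.05.

## Synthetic data

The tabular generator draws labels first (case-control, default balance
0.5), then features: the planted informative columns are unit-variance
Gaussians whose class means differ by the standardized effect size;
nuisance columns are standard Gaussians in equicorrelated blocks (shared
factor construction, default ρ = 0.5 in blocks of 10) to mimic the
redundancy of filtered-image features; a heavy-tailed option (scaled t₃)
exists behind a flag. Reference conditions: 150 patients × 400 features,
10 informative at effect 1.0. The phantom generator produces a spherical
lesion (default radius 12 mm, contrast 5, background SUV 1, Gaussian noise
0.2 SUV) on anisotropic PET-like voxels.

What the generator does **not** emulate: real PET texture covariance, the
dependence between features extracted from the same underlying image,
scanner effects, non-Gaussian radiomics marginals, or label noise in the
Gleason ground truth. Passing the recovery tests shows the pipeline's
machinery — resampling stability, selection frequency, redundancy
filtering, ensemble aggregation — behaves correctly under known signal; it
does not certify clinical performance on patient data.

## Problem sizes and numerical choices

Tests run the loop at scaled-down sizes chosen to keep the whole suite
comfortably interactive: the headline recovery run uses the reference
table with 10 repetitions and budget 15; unit tests use 60–80 patients
with 30–60 features and 2–3 repetitions; the phantom for extraction checks
is a 24³ grid. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, making every artifact a pure
function of (inputs, seed); the determinism test verifies byte-identical
frequency tables, subsets and metric tables across repeated runs.

## Known limitations

* The extractor implements the standard feature definitions independently;
  individual feature *values* are not bit-compatible with any particular
  third-party extractor (aggregation conventions differ across tools), only
  the taxonomy, counts and qualitative behavior are pinned by tests.
* The GP tuner is a compact implementation (random candidate pool for the
  acquisition argmax); for very large budgets a dedicated optimizer would
  be more sample-efficient.
* `SVC(probability=True)` performs the internal Platt calibration; its
  five internal folds are independent of the shared plan folds.
* The Friedman p-value uses the χ² approximation, adequate at ≥ ~10
  repetitions; exact permutation p-values are not implemented.
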