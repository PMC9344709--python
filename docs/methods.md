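# Methods

## ADC estimation

The mono-exponential decay model S_b = S₀·exp(−b·ADC) is inverted per
pixel as ADC = (1/n)·Σ_{b>0} ln(S₀/S_b)/b over the n positive-b images.
Two sign conventions are possible — summing ln(S_b/S₀)/b yields negative
values for decaying signal — and this package uses the positive form,
the convention under which ADC values are reported throughout the DWI
literature. The b=0 term is excluded (division by zero); with the
default two-image protocol (b = 0 and 1000 s/mm²) the average reduces to
a single ratio. Intensities are clamped at a floor (default 10⁻⁶ × max
S₀, configurable) so logarithms stay finite at pathological zero-signal
pixels. The estimator is exact on noiseless model-generated data and
invariant to any common positive rescaling of the images, both asserted
in tests. Multi-exponential/IVIM decay, eddy-current and motion
correction are out of scope.

## Moments

Within the ROI (row-major pixel scan), the mean and the standardized
central moments m₃/σ³ (skewness) and m₄/σ⁴ (kurtosis) are computed with
the empirical frequency 1/N per pixel (biased estimators). The
standardization makes kurtosis of a normal distribution converge to 3,
the classical reference value; the raw central moments would instead
scale with the data's units, which is not a usable feature across
patients. A zero-variance ROI makes both moments undefined and the
slice is flagged invalid rather than imputed.

## Quantization and GLCM

Co-occurrence statistics need discrete gray levels. In-mask ADC values
are binned linearly between their min and max into n equal-width bins
(default n = 16 — small hand-drawn ROIs need coarse binning to populate
an n×n matrix; configurable), with the maximum mapped to level n−1 and a
constant ROI mapped to level 0. Because binning is min–max based, every
downstream texture feature is invariant under monotone affine rescaling
of the ADC values.

The GLCM at displacement δ counts ordered level pairs (k, l) over all
pixel positions where **both** endpoints lie inside the ROI mask and the
displaced position is in bounds; out-of-ROI neighbors contribute
nothing. Accumulation is symmetric by default (pair + transpose), the
common Haralick practice, which makes the i-sided and j-sided marginal
means and variances coincide; both columns are still emitted for
interface fidelity. The matrix is normalized to sum 1; raw counts stay
retrievable. Pixel-pair distance defaults to d = 1.

Nine statistics are evaluated on the normalized matrix P over indices
i, j ∈ [0, N−1]: marginal means μᵢ = Σ i·P_ij and μⱼ, marginal variances
σᵢ² = Σ P_ij (i−μᵢ)² and σⱼ², energy Σ P², entropy −Σ P ln P (natural
log, 0·ln 0 := 0), contrast Σ P (i−j)², homogeneity Σ P/(1+(i−j)²),
correlation Σ P (i−μᵢ)(j−μⱼ)/(σᵢσⱼ), cluster shade Σ P (i+j−μᵢ−μⱼ)³ and
cluster prominence Σ P (i+j−μᵢ−μⱼ)⁴. Correlation is undefined when a
marginal variance is zero (constant texture) and is reported as absent
— never silently 0 — which flags the slice invalid. Features are
computed per orientation at offsets (0,d), (−d,d), (−d,0), (−d,−d) and
the **feature values** (not the matrices) are averaged, making the
averaged set invariant under 90° image rotation (asserted in tests).
Range invariants (energy, homogeneity ∈ (0,1]; entropy ∈ [0, 2 ln N];
correlation ∈ [−1,1]; contrast, prominence ≥ 0) are property-tested,
and the pair counting is verified exactly against a brute-force
enumeration oracle and against scikit-image's `graycomatrix` on
full-mask fixtures (scikit-image has no mask support, which is why the
masked GLCM is implemented here).

## Feature table and normalization

Each slice yields 16 attributes (14 image features + age + gender
∈ {0,1}, female = 0) with a binary malignant/benign label, exchanged as
CSV with a fixed column contract; rows with missing or invalid fields
are dropped with a logged count. Normalization is min–max,
Xₙ = (X − X_min)/(X_max − X_min), with parameters fitted on **training
rows only** to avoid test-set leakage; out-of-subset values may fall
outside [0,1] and are not clipped. A z-score variant is available
(`method="zscore"`) for sensitivity analysis. Gender's min–max transform
is the identity whenever both genders appear in the fitting subset.

## ANOVA F-test selection

Each feature is scored by the one-way F statistic (between-class mean
square / within-class mean square, df (1, N−2)) against the label. A
single F-test is deterministic, so repetition is made meaningful by
scoring each of the 5 repeats (default) on a stratified random
subsample of 80% of the rows and averaging — a surrogate that keeps the
estimator centered while inducing the run-to-run variability a repeated
protocol reports. Selection drops the k lowest mean scores (default
k = 2) rather than applying an absolute threshold, because observed
score profiles place retained features between the dropped ones'
neighborhood and any threshold would be arbitrary; ties break by column
order. Scores are scale-free (affine invariance asserted), and under
label permutation the mean F approaches df₂/(df₂−2) ≈ 1 (property-tested).

## Classification

Malignant is the positive class throughout. The stratified split
reserves round(N × 0.30) rows for testing, apportioned per class by
largest remainder so each class proportion is preserved within one row
(995+604 rows split exactly into 1119 train / 480 test with 299
malignant test rows). Seven classifiers — logistic regression, LDA,
k-NN, decision tree, Gaussian naive Bayes, SVC, random forest — are
compared by stratified ten-fold CV accuracy at library defaults
(logistic regression gets `max_iter=1000` for reliable convergence);
ties go to the earlier, simpler model in that order.

Random Forest tuning samples candidates uniformly (default 100) from
the grid min_samples_split ∈ {2,5,10}, n_estimators ∈ {200,…,1000 step
10}, max_depth ∈ {10,…,100 step 10}, max_features ∈ {3,5,10,20}, scoring
each by stratified 5-fold CV precision or recall on the training rows.
A sampled max_features exceeding the actual feature count (possible
after selection leaves 14 columns) is clamped to it at fit time. The
decision threshold is either fixed (default 0.45; prediction rule:
malignant iff P(malignant) ≥ threshold) or chosen to maximize F1 over
the precision–recall curve's candidate cutoffs — the lowest observed
score plus the midpoints between consecutive distinct scores, which
together realize every achievable prediction set; ties resolve to the
lower cutoff. Metrics (accuracy, per-class precision/recall/F1/support,
macro and support-weighted averages) are computed from the confusion
counts; a zero denominator reports 0 with a logged warning.

## Synthetic cohort generator

The generator emulates a single-site DWI study: 124×124 matrix, b = 0
and 1000 s/mm², 1599 slices at 62.22% malignant by default (the
screened−excluded bookkeeping 1896 − 297 = 1599 and the per-type
composition table ship alongside). Each slice carries one axis-aligned
elliptical ROI (semi-axes uniform on 6–18 px, placed fully inside the
grid; hand-drawn ROI shapes are unknowable, an ellipse is the simplest
area-controlled stand-in). The in-ROI ADC field is mean_adc ×
(1 + heterogeneity_sd × G) where G is white noise smoothed by a Gaussian
kernel of width texture_correlation_length and rescaled to unit
variance — the simplest generator with a tunable GLCM-visible
correlation structure. Background tissue uses a fixed mild texture
around 900×10⁻⁶ mm²/s. Signal is S_b = S₀·exp(−b·ADC) with
multiplicative log-normal noise of sigma noise_sd (default 0.02),
keeping intensities strictly positive so the ADC logarithm is defined.

Default class parameters, chosen once from typical DWI literature
ranges: malignant mean ADC 800×10⁻⁶ mm²/s, correlation length 1.2 px,
heterogeneity 0.20; benign 1400×10⁻⁶ mm²/s, 3.0 px, 0.10. Gender is
Bernoulli with P(male) 0.62 (malignant) / 0.39 (benign), which plants
the class–gender association while reproducing an overall ~53% male
cohort at the default class balance; age is uniform on 12–80 years and
deliberately uncoupled from class. Two presets support experiments:
`well_separated_class_params()` (2× ADC ratio, stronger texture
contrast) for parameter-recovery tests, and `null_class_params()`
(identical classes, equal gender probabilities) for false-signal tests.

What the generator does **not** emulate: brain anatomy, 3-D multi-slice
tumors and intra-patient slice correlation (slices are independent, so
patient-level grouping effects on CV estimates are absent), Rician
noise statistics, scanner artifacts, DICOM metadata. Passing tests
therefore demonstrate that the pipeline recovers planted class
structure of the kind described — not clinical performance on patient
data.

## Problem sizes and numerical choices

The test suite exercises image-level cohorts of 40–120 slices on 48–64
px grids for unit/property tests, a 1000-slice default-geometry cohort
for the end-to-end recovery check (tuned forest ≥ untuned − 0.01, both
≥ majority baseline + 15 points), 100 seeded trials for the
planted-vs-noise ANOVA ranking, and 10⁶ draws for the normal-kurtosis
limit. The end-to-end check uses 8 search candidates with 3-fold inner
CV; the library defaults remain 100 and 5. All randomness flows from a
master seed through named `SeedSequence` substreams (simulate,
selection, split, cv, search, model), recorded in each run's log, so a
config plus seed reproduces a run's outputs exactly.

## Known limitations

- Feature definitions follow the formulas above, not the IBSI
  standard; values are not interchangeable with IBSI-certified
  radiomics tools.
- Quantization to a fixed level count makes features comparable across
  slices only in rank/texture terms, not in absolute gray-level units.
- Kurtosis is reported numerically without a platykurtic/leptokurtic
  label; conflicting labeling conventions exist.
- The ANOVA repetition mechanism (stratified 80% subsampling) is a
  documented modeling choice, not the only way a repeated selection
  protocol could vary.
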