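# Methods

This note documents the models implemented in `noduleclick`, the choices made
where the procedure was genuinely open, and what the synthetic data do and do
not establish.

## Hounsfield conversion and the adaptive threshold

CT slices are handled as stored integer values plus rescale metadata and
converted once, at the boundary of the package, via Hu = B + M·SV. Missing
rescale tags fall back to the identity transform (B = 0, M = 1) with a logged
warning rather than an error, since phantom and fixture files legitimately
omit them; clinical DICOM is expected to carry them.

The segmentation threshold adapts to the clicked pixel through two regressions
and a subtraction:

* **Mean model** — ordinary least squares of the nodule's mean HU on the
  clicked HU (*Start*). The shipped intercept/slope defaults are
  β₀ = −173.34, β₁ = 0.71, the reference coefficients for this model on
  clinically marked nodules; refitting on any calibration CSV is supported.
* **Std model** — the regression family for estimating the nodule HU standard
  deviation from (*Start*, *Avg*) is taken as ordinary least squares on
  (1, Start, Avg): with exactly two named predictors and no stated
  interaction structure, plain multiple linear regression is the natural
  reading. Negative predictions clamp to zero so the threshold can never rise
  above the estimated mean. Reference coefficients for this model are not
  available, so `ThresholdCalibration.default()` fits them at call time on
  the package's own synthetic calibration set (n = 400, fixed seed
  20231030); they are fully overridable via `ThresholdCalibration` or the
  calibration JSON.
* **Threshold** — Avg − α·Std with α ≥ 0, default 2. α trades recall against
  precision: the threshold is non-increasing in α and the grown region is
  therefore non-decreasing (asserted as a property test).

## The TM segmenter

Growth takes the 8-connected component of {Hu ≥ threshold} ∩ lung containing
the click. The threshold is a **lower bound only** — dense structures above it
are admissible — because the calibration subtracts spread from the mean and
larger spreads are meant to enlarge the region; no upper bound is defined.

Morphology uses a 3×3 all-ones structuring element, one iteration each, with
everything outside the grid treated as background. Order: erode → noise
removal → dilate. "Noise" is any component not containing the click; if
erosion removed the click's own pixel from every component, the component
with the nearest centroid is kept instead — the least destructive reading,
since the definition presumes the clicked area survives. The dilation is
clipped back to the grown (admissible) region, which keeps the final mask
inside both the lung and the above-threshold set; consequently the TM mask is
provably a subset of the lung mask. Any stage that empties the mask sets
`is_null`, the signal for the fallback — including the degenerate case where
the click survives growth but erosion empties the mask.

Connectivity for noise removal is 8-connected, matching the growth step (the
choice was open; consistency won).

## Candidate fusion and the fallback

A trained detector network is deliberately out of scope; the fallback is a
provider interface mapping (HU image, click) → list of candidate masks. The
shipped provider re-runs the TM chain at α ∈ {1, 2, 3} **without the lung
constraint**, which is exactly what lets it reach juxtapleural nodules the
lung-constrained path cannot; its candidates are nested by construction.
Selection forms U as the union of intersections over *distinct* candidate
pairs (self-intersections excluded) and maximises the raw overlap area
|candidate ∩ U| — normalised variants were rejected to keep the argmax
scale-consistent. Ties break toward the larger candidate, then list order;
with all candidates pairwise disjoint U is empty and the tie rule alone
decides (largest wins). Fallback masks may extend outside the lung; TM masks
may not.

Anchor accounting reconstructs the full-scan count as
Σ_levels ⌈rows/stride⌉·⌈cols/stride⌉ with one anchor per position; the
512×512 / strides {4, 8, 16, 32, 64} default gives 21 824, and the 3×3
click-fixed window over 5 levels gives 45. Per-position counting is the only
convention consistent with both numbers. Window truncation at feature-map
borders is handled when a concrete click is supplied.

## Radiomics-lite features and ranking

21 named features: 11 first-order HU statistics (mean, std, min, max, median,
p10, p90, skewness, kurtosis, energy, entropy on a 32-bin histogram), 6 shape
descriptors (area, perimeter, equivalent diameter, eccentricity, solidity,
compactness = 4πA/P²), and 4 GLCM texture features (contrast, correlation,
energy, homogeneity) averaged over offsets (0,1), (1,0), (1,1), (1,−1). The
GLCM is computed on a 32-level quantisation of the masked HU range within the
mask's bounding box; out-of-mask pixels are assigned a sentinel level whose
rows/columns are dropped, so features are invariant to anything outside the
mask. Features are translation-invariant and deterministic. This is a
reproducible subset, not parity with commercial radiomics inventories — the
tested contract is selection behaviour, not the feature count.

Rankers: chi-squared (features min-max scaled to [0,1] for that ranker only,
as chi-squared requires non-negativity), ANOVA F, information gain with a
single median-split discretisation (the simplest deterministic choice), and
absolute Pearson correlation with the 0/1 label. Constant features score 0
and are flagged degenerate; top-k selection breaks ties by feature name.

## BEED

Down-sampling reads "(m/n) subsets" as ⌊m/n⌋ disjoint majority blocks of
exactly n, remainder discarded and logged — equal-sized balanced subsets
forbid ragged blocks. Member i's AUC is computed on the deduplicated union of
the other subsets (minority rows appear in every subset, so deduplication
matters); AUC uses the rank convention with ties counted ½ and is verified
against a brute-force pairwise-concordance oracle in the tests. Weights are
min-max normalised AUCs; an all-equal AUC vector yields all-ones weights
(unweighted majority vote). Votes are **hard labels** by default — the
procedure sums weighted positive *results* — with probability voting behind
the `soft_votes` flag. The vote sum is normalised by Σw so the 0.5 criterion
is scale-free regardless of member count; the positive call requires the
fraction to *strictly exceed* the criterion. Despite the "boosting" in the
name, training is parallel subset fitting plus weighted voting, not
sequential reweighting, and is implemented as described.

`BeedClassifier` follows the scikit-learn estimator protocol (get/set_params,
clone, `fit`/`predict`/`predict_proba`/`decision_function`, trailing-underscore
fitted attributes) and composes with sklearn model selection; the pipeline's
cross-validation harness uses stratified five-fold splitting — plain random
folds at 160:30 can easily leave a fold single-class.

## Synthetic data

Phantoms place an elliptical soft-tissue body (0 ± 20 HU) on an air background
(−1000 ± 20 HU), two elliptical lungs (−800 ± 40 HU) and disc nodules
(default −300 ± 30 HU); noise is independent Gaussian per tissue class. No
beam hardening, streaks, partial-volume blur or anatomical texture is
simulated: passing phantom tests shows the threshold chain, connectivity and
morphology behave as specified under their statistical assumptions, not that
the defaults are clinically tuned. Juxtapleural phantoms centre the nodule
just outside the lung wall so the disc straddles the boundary and the click
lands outside the lung mask — the designed failure mode of the TM path. The
click defaults to the truth centroid, with a jitter option for robustness
tests.

Calibration sets draw Start uniformly on [−600, 100] HU and generate
Avg = β₀ + β₁·Start + ε (σ_ε = 5 HU) with the reference β, and
Std = 32 + 0.01·Start + 0.01·Avg + η (σ_η = 2 HU), values chosen to keep
nodule spreads in a plausible 20–32 HU band and strictly positive so the
clamp stays inactive during fitting.

Feature tables are two-class Gaussians at the study's 160:30
majority:minority ratio, 10 features of which 4 are informative with a class
mean shift δ. The default δ = 1.6 (σ = 1) was calibrated so that a single
classifier fitted on the raw imbalanced table sits below 0.8 specificity —
the imbalanced regime the ensemble targets; a sweep over
δ ∈ {1.2, 1.6, 2.0, 2.4} gave single-model specificities of roughly
0.51/0.74/0.86/0.94, and 1.6 is the largest separation still inside that
regime. Under these conditions the balanced ensemble raises mean specificity
by ≈ 0.2 while conceding ≈ 0.02 mean accuracy (recomputed by
`scripts/acceptance.py`).

## Problem sizes and numerical notes

Tests and the acceptance script use 192×192 phantoms (nodule radius scaled
proportionally, ≈ 10 px) and 50 replicate tables for the imbalance
comparison; these sizes are the package's choice for a fast, fully
deterministic check suite and do not change any algorithmic constant. All
generators are bit-reproducible from their seeds. Degenerate inputs are
contract-covered: empty masks stay empty through morphology; a seed below
threshold yields a null TM result; single-member ensembles skip the AUC step
with weight 1; zero-weight vote sums fall back to an unweighted majority;
empty-denominator metrics report 0.

## Known limitations

2-D single-slice only (no volumes, no DICOM series assembly); no learned lung
segmenter (a classical HU-based masker is provided for phantoms and demos
only); the shipped fallback provider is a lung-unconstrained re-run of TM,
not a trained detector, so on phantoms whose nodules touch soft tissue it can
overgrow into the body — the candidate-fusion rule and switch semantics, not
fallback mask quality, are the tested contract; binary labels only; no SMOTE
or weighted-loss alternatives inside the estimator.
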