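# Methods

This note documents the models, conventions and numerical choices behind
`pathoscore`, and what the synthetic cohorts do and do not establish.

## Slide processing

Tissue segmentation uses Otsu's criterion on the 256-bin histogram of the
Rec. 601 luminance (0.299 R + 0.587 G + 0.114 B): the returned threshold
maximizes the between-class variance, ties broken toward the lower
threshold, and tissue is the darker side. A slide with a single occupied
gray level is rejected as degenerate.

Tiling is a fixed grid anchored at pixel (0, 0), 0-based row-major
coordinates. Source tiles are 1024 px at 40× and 512 px at 20×; 512-px
tiles are upsampled bilinearly to 1024 px so both magnifications share one
output contract. Edge remainders are discarded. A pixel is "white" when
all three 8-bit channels are ≥ 220; tiles with a white fraction strictly
greater than 0.5 are excluded (a tile at exactly 0.5 is retained). Ten
tiles are sampled uniformly without replacement per slide, seeded; slides
with fewer than ten candidates contribute all of them with a warning
rather than failing, which keeps small fixtures usable. The magnification
is carried as explicit metadata, not read from image headers, because
plain PNG/TIFF stand-ins lack objective-power tags.

## Texture features

The feature registry (`pathoscore.texture.FEATURE_REGISTRY`, version
`core-fo-glcm-glrlm-1`) is a documented core radiomics set: 14 first-order,
9 GLCM and 7 GLRLM features, 30 in total. Shape/morphology features are
deliberately omitted — grid tiles carry no segmentation mask — and no
filtered-image (wavelet/LoG) classes are computed.

Discretization is fixed-bin-count: 32 equal-width bins over the observed
[min, max] of each tile, so every feature is invariant to adding a
constant to all pixels. Matrix features use offset distance 1 in the four
2-D directions (0°, 90°, 45°, 135°), symmetric and normalized GLCMs, and
are averaged over directions. Internal moments are population (1/N)
moments; entropy and uniformity use log base 2; GLCM correlation of a
constant tile is defined as 1. Slide-level vectors are the arithmetic
mean over the sampled tiles. Z-scoring uses the training-cohort mean and
*sample* (n−1) standard deviation; zero-variance columns are dropped and
logged. First-order moments are accumulated in float32 with float64
reductions, which matches the float64 definitions to ~1e-4 relative — far
below any biological signal of interest.

## Selection and models

Mutual information is the plug-in estimate on equal-frequency 4-bin
discretizations of continuous features. mRMR uses the classical MID
(difference) criterion, with MIQ behind a flag; ties in any score break
lexicographically on feature name, making selection deterministic and
column-order invariant. RFE refits a linear SVC (C = 1) and drops the
smallest-|w| feature one at a time; the elimination order is logged.

The logistic model is a maximum-likelihood fit (Newton iterations,
tolerance 1e-8, ≤ 100 iterations) with backward stepwise elimination on
AIC = 2k − 2 ln L; the intercept is never dropped. Perfect separation is
detected and reported via a ridge-penalized fallback flagged on the model.
The SVM is a linear soft-margin classifier; probabilities come from Platt
scaling fit on out-of-fold decision values (5 folds, reduced to the
smallest class size when needed). "High expression" is the positive class
everywhere, and the pathomics score is the predicted probability of that
class.

## Validation statistics

AUC is the trapezoidal area over the empirical ROC, identical to the
tie-corrected Mann–Whitney statistic; its variance and CIs come from
DeLong placement values, and two correlated AUCs are compared by the
DeLong z-test. Operating-point metrics use a Youden-optimal threshold
scanned over score midpoints unless a threshold is supplied. K-fold CV is
stratified and seeded, and refits the *entire* pipeline — standardization,
mRMR, RFE, classifier, Platt calibration — inside every training fold;
`k = n` degenerates to leave-one-out. A stratified holdout split is also
provided, since a fixed train/test protocol and tenfold CV are both
legitimate readings of the validation design; CV is the default.
Hosmer–Lemeshow uses equal-count deciles of predicted risk with df = g − 2
(groups emptied by ties are merged and df adjusted). Decision curves are
evaluated on the grid 0.01–0.99 in steps of 0.01 without smoothing.

## Survival

Kaplan–Meier and log-rank statistics come from lifelines; Cox models are
fit by Newton–Raphson on the Efron partial likelihood (Breslow behind a
flag) via statsmodels PHReg, with Wald CIs exp(β ± 1.96 SE). Minimum-p
dichotomization scans the midpoints of adjacent sorted unique marker
values, keeps candidates leaving ≥ 10 % of patients on each side, and
returns the argmin of the two-group log-rank p, ties toward the lower
cutoff. The reported minimal p is *not* adjusted for the multiplicity of
the scan — an inferential caveat inherited from common practice with this
estimator. Subgroup interactions are Wald tests of the product term of
0/1-coded main effects (reference = lexicographically first level). Times
are months throughout; no delayed entry, no competing risks, no
proportional-hazards diagnostics.

## Enrichment

Genes are ranked by Spearman correlation with the pathomics score
(descending, ties by symbol; duplicate symbols keep the highest-variance
row; constant rows get ρ = 0). The stated ranking metric of the original
workflow is ambiguous, so this reading is a documented design choice. The
enrichment score is the signed extremum of the weighted KS running sum
with weight p = 1. Significance uses gene-set (tag) permutation — random
same-size sets from the ranked universe — because the pipeline consumes a
single preranked list; phenotype permutation (re-ranking against permuted
scores) is available behind a flag at higher cost. NES divides ES by the
mean |null ES| of matching sign; the nominal p is the same-sign tail
fraction; the FDR q follows the sign-stratified pooled-null NES
convention. Gates: p < 0.05 and FDR < 0.25. Immune-cell fraction tables
(supplied externally; deconvolution is out of scope) are compared between
PS groups by two-sided rank-sum tests with Benjamini–Hochberg adjustment;
for gene-list correlations the Spearman p is computed by exact rank
permutation when n ≤ 8 patients.

## Synthetic cohorts

The generator plants the statistical structure the analysis assumes:

- **Classes.** Exactly round(prevalence × n) patients are high-marker
  (default prevalence 0.34, matching roughly a third of patients in the
  motivating cohort), at random positions.
- **Marker.** marker = cutoff ± 1.0 + N(0, 0.5) on a log2 scale, with the
  default dichotomization point 4.2784.
- **Survival.** Exponential baseline parameterized by the low-class median
  (14 months); the high class multiplies the hazard by exp(log HR),
  default HR 1.9. Censoring is an independent exponential whose rate is
  solved (Brent) so the expected censored fraction equals the configured
  rate (default 0.2).
- **Slides.** White background (level 245) with smooth random tissue blobs
  covering ~75 % of the slide. The tissue interior is a Gaussian random
  field whose smoothing kernel width is `1.6 · exp(± texture_effect / 2)`
  (wider for the high class): wider kernels give smoother texture and
  directly lower GLCM contrast / raise long-run emphasis, planting a
  texture signal without modeling histology. The field is mapped into an
  eosin-pink-to-hematoxylin-purple palette with the mixing coefficient
  clipped at 0.15 so the brightest tissue stays well below the Otsu split.
  The true blob mask is attached to each slide for mask-recovery tests.
- **Expression.** Signal genes are marker + N(0, 0.7) on the latent scale,
  noise genes are independent; all values are exponentiated to a TPM-like
  positive scale. A GMT file carries the planted set plus random decoys.

Everything derives from a single integer seed; slides render lazily so
large-n cohorts for parameter-recovery simulations never materialize
images.

What the synthetic cohorts do **not** emulate: nuclear morphology, stain
variation and artifacts, pyramidal slide formats, correlated gene modules,
informative censoring, covariate-dependent hazards. Passing tests
demonstrate that the pipeline recovers structure it is designed to detect
under its own assumptions — not that it would reach any particular
performance on real H&E slides.

## Problem sizes and reference runs

The reference synthetic cohort is 78 patients with 2048-px slides at 20×
(16 candidate tiles per slide, of which ≥ 10 survive the white filter at
the default tissue fraction); this is the package's standard demonstration
size. Null-calibration runs (texture_effect = 0) use ten fresh 40-patient
cohorts, whose mean cross-validated AUC estimates chance performance to
about ±0.03. Parameter-recovery simulations use n = 2000 (Cox hazard
ratio), n = 5000 (logistic slope), n = 300 (cutpoint scan) and 20 seeds of
n = 200 (RFE recovery); calibration suites use 500 (Hosmer–Lemeshow),
200 (DeLong) and 500 (log-rank permutation) replicates.

## Known limitations

- The texture registry is a core set; workflows built on large filtered
  feature banks will select from a richer pool and may behave differently.
- Gene-set permutation tests a different null than phenotype permutation;
  with strongly correlated genes it can be anti-conservative.
- The minimum-p cutpoint's naive p-value overstates significance.
- The Platt calibrator is refit per CV fold but still shares the fold's
  training data with the SVM; very small folds can give coarse
  probabilities.
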