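# Methods

This note documents the statistical model behind `battkit`, the synthetic
study conditions it is validated on, and the numerical choices made where
the design was genuinely open.

## Scientific setting

Multi-test neuropsychological batteries for post-stroke aphasia face a
depth/breadth trade-off. Deep ("extensive") batteries measure each ability
with many items and grade severity well, but take many hours; shallow
clinical screeners cover many activities with few items each and can miss
mild deficits. `battkit` implements a data-driven middle path: derive the
latent deficit dimensions of a deep battery, shorten it to a small set of
proxy tests with halved item sets, verify that sensitivity and latent
structure survive the reduction, and map the resulting dimension scores to
brain abnormality.

## Latent-dimension analysis

Scores are percent correct per test (0–100), z-standardised per test with
the n−1 SD convention. Missing raw scores are imputed by the test mean
before PCA and flagged in logs; held-out data are standardised with
training-fold statistics only.

**Dimensionality.** The number of principal components k is chosen by
k-fold (default 5) cross-validated reconstruction error. Within each
held-out patient row, each test entry is deleted in turn and predicted by
least squares from the remaining entries through the training-sample PCA
basis ("element-wise" scheme). Naive row projection would let the deleted
entry predict itself and bias RMSE monotonically downward; the element-wise
scheme removes that leak, giving the RMSE curve a genuine minimum.
RMSE is pooled over folds; ties in the argmin go to the smaller k
(parsimony). On an exactly rank-k noiseless matrix the scheme attains RMSE
< 1e-6 at the true k.

**Rotation.** At the selected k, loadings (test–component correlations)
are varimax-rotated with Kaiser row normalisation (tolerance 1e-8, max 500
sweeps). The rotation engine is the classical pairwise planar-rotation
algorithm with the closed-form optimal angle per factor pair. We avoided
the SVD fixed-point iteration deliberately: on perfectly patterned
loadings it can enter a period-2 cycle and return the unrotated solution
(R's `stats::varimax` exhibits the same stall), whereas each pairwise
rotation increases the criterion monotonically. Components are ordered by
post-rotation variance explained; each component's sign is fixed so its
largest-magnitude loading is positive. Communalities and total variance
explained are invariant under the rotation to 1e-8 and are verified as
such in the tests.

**Scores and generalisability.** Factor scores use the regression method,
`W = R⁻¹ L` with R the observed correlation matrix (pseudo-inverse for
near-singular R), so a patient at the sample mean scores 0 on every
component. Generalisability is the Pearson correlation between observed
and element-wise-predicted z-scores pooled over all cells of a
leave-one-out loop. Component solutions from different batteries are
matched greedily by maximum |r| on shared patients, signs reported.

## Battery reduction

Per rotated component, proxy tests must load ≥ 0.5 on the target component
and ≤ 0.3 in absolute value elsewhere ("high and near zero",
operationalised; both configurable), ranked by target loading; two proxies
per component by default, each test assigned to at most one component.
Clinical-utility preferences, which no algorithm can compute, enter only
as an optional priority list that breaks ranking ties.

Tests longer than 60 items are halved at item level: a single unrotated
first factor is fit to the item-level correct/incorrect matrix (Pearson
correlations of raw binary items, not tetrachorics — this is what a
default package run on raw item scores produces), and the top
⌈0.5 × stratum size⌉ items by loading are retained within each design
stratum, so factorial test structures keep balanced cells. Zero-variance
items get loading 0; ties break toward the lowest item index (loadings are
rounded to 10 decimals first so bit-level jitter cannot reorder truly
identical items). Retained items then rescore the test as exactly
100 × correct/retained.

## Normative comparison

Cutoffs are control mean − k·SD per test (default k = 2, n−1 SD); a score
exactly at the cutoff counts as intact (documented boundary rule,
configurable). For each matched pair of tests the comparison reports
percent intact/impaired per test, squared Pearson correlation, and both
directional miss percentages over the shared patients. Directional miss
columns are summarised with means, n−1 SDs and an exact two-sided Wilcoxon
signed-rank test: zero differences dropped, midranks for ties, and the
null distribution of the signed-rank sum obtained by dynamic-programming
convolution over the (doubled) ranks — identical to enumerating all 2^m
sign assignments — for m ≤ 25, with a continuity-corrected normal
approximation above. The two-sided p doubles the smaller tail.
Demographic profiles of misclassified patients are medians of full-sample
z-scores (n−1 SD), with no significance test by design.

## Lesion mapping

Analyses run inside a mask of voxels abnormal (≥ `binarize_at`, default
0.3 on the [0,1] abnormality scale) in at least 10% of patients, boundary
inclusive. Group lesion-profile comparisons use a two-sided Fisher exact
test per voxel.

**VBCM.** At each masked voxel a linear model regresses abnormality on all
component scores simultaneously plus covariates and an intercept.
Clusters are formed from the one-sided t map (default direction: more
abnormality with lower score) at voxel p < .001, face (6-neighbour)
connectivity. Cluster-extent family-wise error is controlled by
permutation of the maximum cluster size under the Freedman–Lane scheme:
residuals of the reduced model (all predictors except the one under test)
are permuted and re-added to the reduced fit. This replaces random-field
theory with a distribution-free procedure carrying the same error-rate
guarantee, verified here by null simulation. p-values use the add-one
estimator, so p ≥ 1/(1+n_perm) always.

**RVR.** Component scores are predicted from the masked voxel pattern by
relevance vector regression: a linear kernel over patients (features
mean-centred and the kernel scaled by training-fold statistics only), a
bias column, per-weight precisions α and noise precision β updated by
type-II maximum likelihood. Weights with α > 1e9 are pruned to exactly
zero. Convergence is declared when the largest log-α change falls below
1e-6 or the marginal log-likelihood plateaus (relative change < 1e-8);
the second criterion is needed because near-equivalent solutions (two
correlated kernel columns sharing a weight) produce alpha limit cycles or
glacial drifts along an evidence plateau that the log-α criterion alone
never exits. Exceeding 2000 iterations raises an error with diagnostics.
Performance is the Pearson correlation between observed scores and
leave-one-out predictions (full refit per fold); inference shuffles the
target, reruns the complete LOOCV per shuffle, and uses the add-one
permutation p. "Lesion-volume correction" residualises the behavioural
target on lesion volume (least squares with intercept) before fitting.

## Synthetic study conditions

Real cohorts of this kind are ethics-restricted, so validation uses a
generator whose structure matches the analysis assumptions:

- **Cohort**: default 75 patients (40-patient subgroup scenario
  available), independent standard-normal latent abilities on 4 orthogonal
  factors (phonology, semantics, executive, speech quanta).
- **Extensive preset**: 22 tests. Two designated proxies per factor
  (loading 0.85, propensity noise SD 0.3), seven noisier single-factor
  tests (0.6 / 0.55) and seven mixed-loading tests, because real tasks are
  never factor-pure. A test's percent score is the bounded affine map
  clip(center + slope·η, 0, 100) of its noisy propensity
  η = loading·latent + noise. Noise levels were fixed once so that
  leave-one-out generalisability of the 4-component solution lands in the
  high-0.8s, the band reported for comparable deep aphasia batteries, and
  were not revisited.
- **Items**: each test decomposes into items with graded difficulties
  (equally spaced quantiles within each design stratum) and log-normal
  discriminations. round(score × n_items/100) items are marked correct —
  those with the highest noisy two-parameter probit propensities — so item
  sums reproduce the test score to within rounding while easier and more
  discriminating items are passed first. The 96-item synonym-judgement
  analogue carries a two-cell factorial design.
- **Controls**: 30 by default, near ceiling (mean 97, SD 1.5), no deficit
  factor.
- **Shallow preset**: 12 subtests of 8 items with a compressed
  ceiling-heavy score map (center 88, slope 9), reproducing the reduced
  dynamic range of clinical screeners.
- **Abnormality volumes**: one disjoint spherical region per factor on a
  small shared grid (default 14³); each region holds a smooth radial blob
  with peak amplitude 1 − Φ(latent), i.e. worse ability ⇒ more abnormal
  tissue, over U(0, 0.05) baseline noise. Lesion volume is the voxel sum.

The generator reproduces the *statistical* structure the pipeline assumes
— graded orthogonal deficits, factor-specific damage — not realistic
vascular anatomy, spatial lesion correlations, or the content of any
copyrighted test. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated model, not performance on
real clinical data.

## Simulation sizes and numerical tolerances

Validation problem sizes were chosen to keep the whole suite comfortably
interactive: 25 seeds for dimensionality selection and generalisability
bands; 50 seeds for loading-recovery and proxy-recovery rates; VBCM null
calibration with 100 replicate datasets × 200 permutations on an 8³ grid
(n = 30); RVR type-I calibration with 50 replicates × 63 permutations
(n = 12), each permutation rerunning the full LOOCV. Error-rate checks use
the binomial bound 0.05 + 2 s.e. All generators and permutation engines
are pure functions of (configuration, seed); the orchestration layer
derives per-stage child seeds from one master seed via CRC-32-tagged
`SeedSequence`s, so any stage can be rerun in isolation.

## Known limitations

- Oblique rotations, maximum-likelihood factor analysis, and parallel
  analysis are out of scope; k is chosen only by cross-validated RMSE.
- The CV annotation for the maximum candidate k is interpreted as
  k_max = number of tests.
- Item factor analysis on Pearson correlations of binary items
  underestimates loadings relative to tetrachorics when difficulties are
  extreme; rankings, which are all the halving step uses, are robust to
  this.
- The abnormality generator produces one blob per factor region; it cannot
  probe mass-univariate false positives arising from correlated anatomy.
- RVR permutation inference reruns LOOCV per shuffle and is the main
  computational cost; large permutation counts at n = 75 are expensive.
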