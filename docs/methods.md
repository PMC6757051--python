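# Methods

This note documents the statistical procedures implemented in
`ptbmetab`, the assumptions behind the synthetic cohort generator, the
numerical choices made where the method itself is silent, and the
limitations a user should keep in mind when transferring conclusions
from synthetic tests to real data.

## Study design being modelled

A nested case-control comparison inside a pregnancy cohort: women who
delivered spontaneously before 37 weeks (cases) against women who
delivered at or after 37 weeks (controls), with roughly two controls per
case matched on maternal age (±3 years) and BMI (±5 kg/m²). Serum is
assayed by GC-MS at 15 and 20 weeks' gestation; each injection sequence
is organised in analytical batches of about 18 study samples plus 4
pooled-QC injections and one processed blank (negative control), and all
samples carry an internal-standard spike (Alanine-d4). An early-delivery
subgroup (<34 weeks) is analysed against the **entire** term control
group; deliveries between the early threshold and 37 weeks are excluded
from that comparison rather than relabelled. Sites are always analysed
separately.

Case status is never stored: it is derived on demand as
`ga_delivery < threshold`, so the same cohort object supports every
threshold analysis.

## Preprocessing

Order is fixed and recorded in an append-only provenance list (applying
a stage twice, or out of order, raises a `ProvenanceError`):

1. **Internal-standard normalization** — each injection's intensities
   are divided by that injection's IS value; the IS channel is then
   dropped. This removes per-injection recovery/volume variation exactly
   when that variation is a common multiplicative factor.
2. **Batch median centering** — multiplicative, per compound, on the raw
   (pre-log) scale: values in batch *b* are scaled by
   (global study-sample median)/(batch-*b* study-sample median).
   Medians use study samples only; QC and blank rows are transformed
   with their batch's factor but never contribute to it. A batch median
   of zero leaves that compound uncentered, flagged. The multiplicative
   form commutes with IS division and is exact for log-normal batch
   effects; whether a given real dataset was centred additively on the
   log scale or multiplicatively on the raw scale is typically not
   reported, so the choice is recorded in the provenance rather than
   asserted as universal.
3. **Contaminant filter** — a compound is removed when its mean blank
   intensity reaches `ratio_threshold` (default 0.5) of its mean
   study-sample intensity. No numeric convention is standard here; 0.5
   is deliberately permissive and configurable.
4. **Presence filter** — compounds detected in fewer than 70% of study
   samples are dropped; remaining zeros become missing values. Zeros in
   GC-MS peak tables are censoring artefacts more often than true
   absences, and carrying them into logs or ratios would manufacture
   outliers. Missing cells are excluded pairwise by the rank test.
5. **Ratios and logs** — 20w/15w ratios are formed per subject on the
   raw scale after normalization (subjects missing either timepoint are
   dropped and counted); logs (base e for modelling, base 2 for plots)
   come last.

## Univariate screen

Two-sided Mann-Whitney tests per compound, per comparison (15w, 20w,
ratio). The exact null distribution is enumerated when the combined
sample size is ≤ 20 and there are no ties; otherwise the normal
approximation with tie and continuity corrections is used — at the
design sizes (~55 vs ~110) the approximation is standard. Direction is
the sign of the case-control median difference, reported post hoc.

FDR control is Benjamini-Hochberg within each comparison: *m* equals the
number of compounds retained in that comparison after filtering. The
per-comparison family is the convention that reproduces published
q-values computed at m = 176.

Because the test is rank-based, the screen is invariant to any monotone
transform of intensities — screening raw or log matrices gives identical
p-values (a property test enforces this).

## Clinical and augmented logistic models

Baseline-table tests: Mann-Whitney for continuous covariates; for 2×2
tables the continuity-corrected χ² when all expected counts are ≥ 5 and
Fisher's exact test otherwise; smoking is tested both as a 3-category
table and as current-vs-never.

Model selection is two-phase: (1) a bidirectional stepwise search
minimizing AIC, starting from the intercept-only model, applying the
single best add-or-drop move per step; (2) backward elimination of
terms with Wald p > 0.05 (for multi-column factors the smallest p among
the term's dummies stands for the term). Every AIC evaluated and every
elimination is kept in a trace attached to the fit, so the greedy path
is auditable step by step; tests verify each chosen move was locally
optimal against the enumerated alternatives. Matching variables (age,
BMI) are excluded from the candidate set by default — they are design
variables, balanced by construction — but the candidate list is an
argument.

A metabolite enters the selected clinical model as natural-log
intensity, z-scored (mean 0, SD 1) over exactly the subjects entering
the refit, so its odds ratio is per 1 SD of log intensity in the
analysis sample. A second metabolite whose log intensity correlates
|r| > 0.8 with a column already in the model triggers a collinearity
flag; the fit is still returned (correlated trios are exactly the
situation of interest). Perfect or quasi-separation is flagged on the
fit object, never silently ignored.

The threshold-sensitivity analysis refits the clinical+metabolite model
with cases redefined at 36, 35 and 34 weeks (controls remain term
deliveries); thresholds leaving fewer than 5 cases are flagged rather
than fit.

## Permutation tests

All permutation machinery shuffles labels with group sizes fixed and
uses the add-one estimate `p = (1 + #{at least as extreme})/(1 + B)`,
whose floor is `1/(B+1)` — 0.001 at B = 1000. Ties count as extreme
(conservative). Replicate *k*'s shuffle depends only on the master seed
and *k*, so results are bit-reproducible.

* **Linear-predictor difference** — statistic D = mean η in cases −
  mean η in controls from the logistic fit; the same model formula is
  refit to every permuted label vector. A quasi-separated refit still
  yields a well-defined D and is included (D is a deterministic function
  of the permuted data, so exactness is preserved); only refits that
  error out count as failures, and more than 1% of failures aborts the
  test.
* **Random-forest OOB error** — the observed statistic is the
  out-of-bag misclassification rate of a forest grown on the real
  labels (defaults: 500 trees, √p features per split); each replicate
  grows a fresh forest, with its own derived seed, on shuffled labels.
  One-sided: observed error *less* than permuted.
* **sPLS-DA BER** — see below; the full component-selection procedure is
  rerun inside every replicate to keep selection bias symmetric.

## Sparse PLS-DA

Two classes are encoded as a column-centred indicator matrix Y; columns
of X are centred and scaled to unit **population** SD (this makes the
fit exactly invariant to sample replication). Per component, the
dominant left singular vector of the deflated cross-covariance X′Y is
sparsified by keeping the `keepX = 5` largest-magnitude entries and
renormalizing to unit norm (the hard-threshold member of the sparse-PLS
family — it reproduces "five predictors per component" exactly, unlike
a soft-threshold penalty whose support size floats). X and Y are
deflated by regression on the component score, so successive scores are
orthogonal. There is no random initialization: the SVD of a p×2 matrix
is computed directly, with a deterministic sign convention.

Prediction projects new samples through the stored weights and
deflation loadings and assigns the nearest class centroid under the
Mahalanobis metric of the pooled within-class score covariance; a
singular covariance is ridge-regularized with ε = 1e-8 × trace and
flagged.

The candidate block concatenates the clinical design (binary covariates
0/1, factors dummy-coded, all scaled like every other column) with log
15-week intensities, log 20-week intensities and log 20w/15w ratios;
missing cells are mean-imputed before fitting. Component count (1–3) is
chosen by the balanced error rate averaged over 10-fold × 10-repeat
stratified CV; ties break toward fewer components. When the smallest
class is smaller than the fold count, folds are reduced with a warning.

One behaviour worth knowing: under a global null the cross-validated
BER of a nearest-centroid rule sits slightly **above** 0.5, because
holding a sample out shifts its own class centroid away from it. The
effect is symmetric between observed and permuted data, so the
permutation test stays calibrated (verified empirically in the
acceptance suite), but a null BER of 0.55–0.65 on small folds is not a
bug.

## Synthetic cohort generator

The generator exists to give every downstream stage a known truth. Its
defaults encode the study conditions: 55 cases with two matched controls
each; gestational age at delivery drawn as 37 − Gamma(1.5, 1.5) weeks
for cases (median ≈ 35.3, lower tail to ~25) and truncated
Normal(40.3, 1.3) for controls; binary covariates drawn in controls at
their stated prevalence and in cases at the prevalence implied by the
configured odds ratio; controls matched by jittering the case's age and
BMI within the tolerances. The default site plants vaginal bleeding at
21% control prevalence with OR 2.7, and a trio of compounds at 20 weeks
with pairwise noise correlation 0.9 and a mean log-intensity shift of
ln(1.9) control-SDs — so the per-SD odds ratio of each trio member is
1.9 by construction.

Intensities are log-normal: per-compound baselines μ_j ~ N(10, 1.5²)
(arbitrary peak-area units), biological noise SD 0.4 on the log scale,
a per-batch per-compound multiplicative factor exp(N(0, 0.3²)), and a
per-injection recovery factor exp(N(0, 0.15²)) shared by all compounds
of that injection. The IS channel carries the recovery factor only —
that is precisely the variation an identically-spiked internal standard
can see — which makes IS normalization strictly variance-reducing and
batch centering exactly correct in expectation. Contaminant compounds
additionally appear in blanks at sample-comparable intensity. QC
injections are pool-like (tight 0.05 log-SD around the baseline).

What the generator does **not** emulate: retention-time drift, peak
co-elution and integration error, missing-not-at-random censoring of
low-abundance peaks, instrument sensitivity differences between sites
(beyond configuring fewer compounds), and any correlation structure
among the non-planted compounds. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean multiplicative
error model, not robustness to every GC-MS pathology.

### Power at the default effect size

A planted per-SD OR of 1.9 (standardized log shift 0.642) at 55 vs 110
puts the trio right at the screen's detection limit: the probability
that *all three* compounds clear BH at q < 0.05 against m ≈ 171 nulls is
close to a coin flip even with all technical noise removed, and a little
below it through the full pipeline (residual batch-median estimation
noise). The acceptance suite measures this recovery rate over 50 seeds
and the result should be read as a power statement about the design,
not a defect of the screen; the per-SD OR confidence-interval coverage
(≥ 90% of seeds) and the mean AUC gain (> 0) are the stable recovery
checks at this effect size.

## Problem sizes used by the test and acceptance suites

Desk-scale runs keep the statistical content while staying small: the
null-calibration suite uses 200 cohorts of n = 60 with 8 compounds,
B = 99 permutations for the linear-predictor test, B = 39 for the
60-tree forest test and B = 39 for the sPLS-DA test (5 folds × 2
repeats, up to 2 components) — the add-one p-value is exact at any B,
so only the granularity of the p-scale changes. Parameter recovery runs
50 full-size cohorts (165 subjects × 176 compounds). The acceptance
script analyses one full-size synthetic site with B = 1000
(linear-predictor), B = 500 (forest, 100 trees) and B = 100 (sPLS-DA
with the full 10×10 CV).

## Known limitations

* Unconditional logistic models are used for a matched design, matching
  the analysis being reproduced; a conditional-logistic variant is out
  of scope.
* ROC curves and AUCs are in-sample; no DeLong or bootstrap inference
  and no external validation machinery.
* The sPLS-DA deflation and thresholding follow one member of the
  sparse-PLS family; other implementations differ in detail, which is
  why the dense limit (keepX = p), where all variants coincide with
  classical PLS1, is the cross-checked anchor.
* The BH procedure assumes the per-comparison family is the right
  multiplicity unit; pooling across timepoints/ratios would roughly
  triple m and is a one-line change for users who prefer it.
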