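# Methods

## Scope and data model

`radage` analyses processed, log2-scale expression matrices (genes × samples)
with per-sample covariates: age in years, absorbed dose `D_T` in Gy, sex,
batch/dataset id, and — for the disease cohort — disease, ethnicity and a
train/test/validation split. Doses are binned following the CDC radiation
hazard scale: control (`D_T = 0`, code 0), low (`0 < D_T < 0.5`, 1), medium
(`0.5 ≤ D_T < 1`, 2), high (`D_T ≥ 1`, 3); both interior boundaries are
left-closed exactly as written. The young/old dichotomy is inclusive at the
cutoff: a sample is *young* iff `age ≤ a`.

Expression is assumed already log2; a guard warns when the matrix maximum
exceeds 30 (likely linear scale) and applies `log2(x + 1)` only when asked.

## Preprocessing

**Outliers.** The paper-style "outliers were removed" step is made concrete
as a robust multivariate rule: samples are projected onto the first two
principal components, and a sample is flagged when its Euclidean distance
from the centroid exceeds `median + k·(1.4826·MAD)` of the distance
distribution, `k = 6` by default. This is deliberately conservative: a
homogeneous cohort is flagged-free in ≥ 95% of seeds, while a sample shifted
by several log2 units on all genes is always caught.

**Batch removal.** Per gene, OLS with intercept, protected biological
covariates (age, dose) and sum-to-zero batch contrasts is solved from the
normal equations for all genes at once; the fitted batch component is
subtracted. With sum-to-zero coding the operation is exactly idempotent,
protected-covariate estimates are unchanged by construction, and with no
covariates it reduces to per-batch mean-centering plus the unweighted mean of
batch means. A batch perfectly confounded with a protected covariate is an
error naming the offending covariate rather than a silent absorption of
biology. Constant covariates (e.g. dose in an unirradiated cohort) carry no
batch-protectable signal and are skipped.

**Probe collapse.** Default rule keeps the probe with maximal variance across
samples (the common microarray default); mean-collapse is available.

## The age-cutoff scan

For each candidate cutoff `a ∈ [21, 65]` (cutoffs leaving fewer than 4
samples in the minority class are skipped and recorded) and each panel gene:

- Welch *t*-test of young vs old with `log2FC = mean(young) − mean(old)`.
  Welch is the default because cohort variances are not assumed equal; a
  pooled-variance option exists.
- Balanced-subsampling AUC: per permutation, the majority class is sampled
  without replacement down to the minority size *m*; the balanced set is
  split 60/40 train/test, stratifying on age quartiles within each class so
  both halves keep the age distribution; the classifier is oriented on the
  training half; ROC AUC of the oriented expression score is recorded on
  both halves. Means over `n_perm` (default 1000) permutations are reported.

The univariate classifier is a logistic-type score in a single gene. Because
ROC AUC is a rank statistic, every strictly monotone link produces the same
AUC; the only trainable quantity that can change it is the score's
*orientation*, and for a univariate logistic model the sign of the fitted
slope equals the sign of the training-set class-mean difference (the score
equation at b = 0 is proportional to it, and the univariate likelihood is
unimodal). The implementation therefore orients by the training mean
difference and computes AUC by the Mann–Whitney pair count with ties counted
half — numerically identical to refitting a logistic model per permutation,
and fast enough for the full 45 × 12 × 1000 grid in well under five minutes
on one CPU.

Permutation streams are seeded per `(seed, cutoff, gene)`, so any single grid
cell can be recomputed in isolation and results do not depend on evaluation
order.

**Selection rule.** The winning cutoff maximises the number of panel genes
with `p < α` (α = 0.05); ties go to the higher mean test AUC over the
significant genes at that cutoff, then to the smaller cutoff. If no gene is
significant anywhere the cutoff maximising the mean test AUC over all genes
is returned with a `fallback` flag. Note the rule's known fragility: genes
whose expression drifts *smoothly* with age are significant at many cutoffs
and vote for mid-range ones (where the dichotomy is best powered), and at
extreme cutoffs small minority classes inflate variance. With the default
synthetic panel (five step genes at 29 years, three weak linear drifts,
four nulls) the selected cutoff is typically 29 but wobbles by a few years
across seeds — the same instability the empirical procedure faces.

## Differential expression

Each contrast is a per-gene Welch *t*-test with two-sided *p*, BH step-up
FDR computed *within* the contrast (the conventional reading of
"FDR-adjusted" for a battery of separately reported contrasts), and
`log2FC = mean(A) − mean(B)`. BH is implemented directly from the step-up
definition (`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1) and is cross-checked
in the tests against both a brute-force evaluation and
`statsmodels.multipletests`. Genes constant in both groups report `t = 0`,
`p = 1` with a warning. Intersection summaries use UpSet semantics: for
every non-empty subset of contrasts, the count of genes significant in
exactly that subset. Dose trends are the sign profile of successive bin-mean
differences, e.g. `(−,+,+)` for a gene down at low dose then rising.

## Interaction screen

Per gene, OLS of `y = b0 + b1·age_term + b2·rad + b3·age_term·rad + ε` with
`rad` the ordinal bin code 0–3 (a continuous-Gy option exists but the
ordinal code is the default, matching the 0/1/2/3 bin labelling) and
`age_term` either centred age in years or the young indicator at the selected
cutoff. Centering is for numerical conditioning only; the interaction test is
invariant to affine re-centering of age (verified numerically in the tests).
`p_interaction` is the two-sided *t*-test on `b3` with `n − 4` residual df.
The screen keeps genes at **raw** `p < 0.05` — deliberately not
FDR-adjusted, in contrast to the contrast battery; the asymmetry is a
faithful reproduction of the screening rule this pipeline packages, and the
full per-gene table is always returned so users can re-threshold.

Ranking for preranked enrichment: the default metric is
`sign(log2FC_radiation) · (−log10 p_interaction)` with `log2FC_radiation =
mean(irradiated) − mean(control)` and `log2FC_age = mean(young) − mean(old)`
reported alongside; per-fold-change ranked lists are also exported since a
single combined metric is not the only defensible choice. Scores at `p = 0`
are capped at ±308 (float64 underflow bound). Ties order alphabetically, so
`.rnk` files are byte-stable.

## Disease evaluation

One-vs-rest Welch tables are computed per factor level (disease, ethnicity,
sex) within each split; two-level factors yield a single table (the other
level is its mirror). Ethnicity levels with fewer than 4 samples in any
split are merged into `other` first — singleton levels cannot support a
two-sample test or a factorial cell. The cross-split filter keeps a gene iff
in *every* required split it is significant (`p < 0.05`) **with**
`|log2FC| > 2` in at least 2 distinct one-vs-rest test cases, pooled across
the three factors. The gate is on the absolute log2 fold change by default
(candidate genes' directions are not fixed a priori); a signed-only option
exists, as does a raw-fold-change reading for users who interpret
"fold change greater than two" on the linear scale.

The factorial model `gene ~ disease * ethnicity * sex` uses full treatment
coding with greedy removal of interaction columns that correspond to empty
cells or are otherwise collinear (removals are recorded per gene). The
three-way *p* is the partial *F* comparing the full model to the model with
all main effects and two-way interactions; each two-way block is tested
within the all-two-way model and each main block within the main-effects
model. A partial *F* on a block is preferred over a single-coefficient *t*
because factors have more than two levels; on 2×2×2 designs the two
coincide, which the tests verify against classical cell-means ANOVA
arithmetic and against `statsmodels.anova_lm`. Saturated designs (zero
residual df) are an error advising level merging. Genes are tiered by the
deepest significant stratum: three-way, then any two-way, then any main
effect.

## Synthetic cohorts: what they emulate and what they do not

The generator produces additive log2-scale Gaussian data:
`y = baseline + age_term·age_effect + dose·dose_effect +
age_term·dose·interaction_effect + batch_shift + N(0, σ²)`, with `age_term`
centred age (linear mode) or the young indicator (step mode). Ages are
uniform over the design range so every candidate cutoff has support — real
cohorts are not uniform in age, which only makes the synthetic scan *easier*
than the field case. Doses are drawn per sample from a discrete Gy set with
weights; ex-vivo repeated-exposure designs can carry donor ids, but all
analyses treat samples as independent, matching the unpaired tests
throughout the pipeline.

Default designs mirror the multi-study layout the pipeline targets: an
aging cohort of 76 + 301 samples (ages 21–69, one batch shift), irradiated
cohorts of 20 + 48 + 95 samples with bin occupancies 58/24/48/33 across
{0, 0.1, 0.5, 2} Gy, an interaction cohort of 143 samples, and a 236-sample
disease cohort split 93/102/41 with factor-level weights matching the
marginal composition (control-heavy disease mix; Caucasian/African/Indian
subcontinent dominating ethnicity; mild female excess). Default effect
sizes were chosen once for realism: panel step effects of 0.6–1.0 log2
units on five genes with weak linear drifts (±0.006–0.009 log2/yr) on three
more, dose slopes of 0.6 log2/Gy on a 40-gene block, interactions of 0.8
log2 units on a 20-gene block, and disease markers with ±3 log2 shifts along
two demographic axes each (so the two-test-case filter rule is satisfiable),
one of them carrying an additional pure three-way cell offset. Marker genes
sit inside the interaction-responsive block, so the end-to-end candidate
count reflects the *joint* power of the screen and the filter — it is
usually 1–3 and can be 0 on an unlucky seed, which is reported, not hidden.

What passing tests therefore show: the estimators recover known additive
effects at realistic sizes, hold their nominal error rates on nulls, and
agree exactly with independent oracles. What they do not show: robustness to
heavy-tailed or heteroscedastic noise, probe-level artefacts, correlated
gene modules, confounded observational age/dose distributions, or platform
effects beyond additive batch shifts — none of which the generator
simulates.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  fans a single global seed out to stages via SHA-256-keyed
  `SeedSequence`s (`stage_seed`), so stages are reproducible in isolation
  and all derived seeds stay below 2³¹.
- The 60/40 split rounds per age-quartile segment; a class is never left
  without at least one train and one test sample.
- Equal expression values in an AUC comparison count half (Mann–Whitney
  convention); constant genes define AUC = 0.5 with a warning.
- The test suite runs the heavy simulations at reduced but still decisive
  sizes — the cutoff-recovery check uses 50 replicates of n = 300 with 50
  permutations per cell, the null calibrations 1000 replicate fits — sizes
  chosen so the whole suite completes in a few minutes while keeping every
  check's power high.
- `run_pipeline` writes a manifest with SHA-256 checksums; identical
  config + seed reproduces `summary.json` byte for byte.

## Limitations

- The cutoff-selection rule is a count-then-AUC heuristic, not an inference
  procedure; no uncertainty is attached to the selected age.
- The interaction screen's raw-*p* threshold does not control FDR; the union
  list size scales with the gene count tested.
- An optional integration path for the original public GEO series this
  layout mirrors (series-matrix reader plus the same pipeline) is
  documented, but no network access is attempted anywhere and no test
  depends on it.
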