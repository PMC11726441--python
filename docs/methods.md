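# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `dietbiome`.

## Data model and scales

Abundance tables are samples × features on the **percent** scale (the
merged-profile convention of taxonomic profilers): values ≥ 0, per-sample
sums ≤ 100, possibly < 100 where an unclassified fraction was dropped
upstream. All variance-stabilizing work happens on the arcsin-square-root
transform `t = asin(√(a/100)) ∈ [0, π/2]`, applied at the point of use;
abundances are never silently rescaled. Samples present in an abundance
table but missing from metadata are dropped with a warning; missing
covariate values cause listwise deletion for the affected model only, so
per-analysis n's can differ.

## Differential abundance

For each cohort and feature, OLS of `t` on the diet indicator (comparison
vs reference) plus sex (dummy), age and BMI. The adjusted Cohen's *d* is the
diet coefficient divided by the residual SD — the conventional
linear-model-to-SMD conversion, which reduces exactly to the classical
pooled-SD Cohen's *d* with no covariates (unit-tested against that closed
form). Its sampling variance uses the standard approximation
`(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`. Wald p-values use a t reference with the
residual degrees of freedom (the normal reference differs negligibly at the
cohort sizes involved; t is the conservative choice).

Per-cohort effects are pooled by the moment-based DerSimonian–Laird
random-effects estimator; τ² is truncated at zero, `I² = max(0, (Q−(k−1))/Q)`
in percent, and a single cohort degenerates to itself with τ² = 0 and I²
reported as 0. The 95% CI is `pooled ± 1.96·se` (normal approximation,
consistent with Wald-z reporting). Two BH families are kept: per-cohort
Wald p's across features, and pooled p's across features within each
meta-analysis; q < 0.1 defines significance. Features that are degenerate
in a cohort (all-zero or zero residual variance in the pair subset) are
skipped in that cohort rather than imputed, and the per-feature `k` records
how many cohorts were pooled. Cohorts with fewer than 3 samples in either
diet group are skipped entirely.

Pathway tables pass through the same machinery after a pre-filter that
drops unmapped/unintegrated rows and any pathway whose nonzero prevalence
falls below 0.05 in at least one diet pattern; a coverage filter (mean
coverage ≥ 0.2) applies when a per-sample coverage table is available,
since coverage is produced by the functional profiler, not by this package.

## Correlations

Partial Spearman: x, y **and every covariate column** are rank-transformed
(average ranks on ties), the ranked x and y are residualized on the ranked
covariates by least squares, and the statistic is the Pearson correlation
of the residuals. Ranking the covariates makes the adjustment remove
monotone — not merely linear — confounding; this is the standard Spearman
analogue of partial correlation and is required for the property that
variables which are exact monotone functions of a covariate decorrelate
after adjustment. Because Spearman is rank-invariant, the arcsin-sqrt
transform of abundance is immaterial here; it is applied anyway for
consistency with the SMD stage.

Pooling uses Fisher Z: `z = atanh(ρ)` with
`se = 1/√(n − 3 − k_cov)` by default — the partial-correlation
degrees-of-freedom correction (k_cov = 3 for sex/age/BMI). The classic
`1/√(n − 3)` is available as `df_mode="classic"` for fidelity with tools
that pool plain Fisher-Z; the partial-corrected default is the statistically
correct variance and the two differ by < 2% at n ≥ 150. The pooled z and CI
back-transform through tanh, so the CI always lies inside (−1, 1).
Consumer-population rules restrict each food group's correlations to the
diets that consume it; hPDI correlations run within each diet pattern
separately.

## PERMANOVA

Sequential (Type-I) partitioning of the Gower-centered matrix
`G = −½ J D² J`: terms enter in caller order (sex, age scaled, BMI scaled,
diet last), each term's sum of squares is the increment of `tr(H G)` for
the growing hat matrix, and `F = (SS_k/df_k)/(SS_res/df_res)`. Permutation
p-values freely permute sample rows of `G` (no restricted blocks),
`p = (1 + #{F* ≥ F})/(n_perm + 1)` with 999 permutations by default, so the
smallest attainable p is 0.001. The one-term case is cross-checked against
scikit-bio's one-way PERMANOVA pseudo-F in the tests. Numeric terms are
standardized; a term that adds no rank raises a singularity error.

## Alpha diversity and the outlier rule

Observed richness counts features with strictly positive abundance. The
outlier rule retains samples inside the central 95% percentile interval
(2.5th–97.5th) of the richness distribution, pooled across cohorts by
default with a per-cohort option. A confidence-interval-of-the-mean reading
of "95% interval" would remove nearly every sample at large n, so the
percentile interval is the only self-consistent interpretation; with fewer
than 20 samples no filtering is applied. Dunn's pairwise tests use
rank-mean differences with the tie-corrected variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))` and BH adjustment over the pairwise family;
on two tie-free groups the Dunn z equals the normal rank-sum statistic
(oracle-tested).

## Random-forest validation

Forests use 1,000 trees, 10 samples per leaf, no depth limit, Gini, and
`max(1, round(0.10 · n_features))` features per split. Two named profiles
exist: `full` (1,000 trees, 10 repeats × 10 folds) and `scaled` (200 trees,
5 × 5) — the scaled profile is the package's desk-scale configuration and
is what the worked examples and the acceptance run use; it leaves AUC means
within noise of the full profile on the synthetic data sizes documented
below. Class imbalance (~92% omnivores) is handled by stratified folds with
no class weighting; a cohort whose minority class cannot fill the requested
folds gets fewer folds with a warning. Cross-LODO support samples are
restricted to the two diet labels under comparison (binary AUC requires it).
Per-test AUC is computed per fold; fold ROC curves are linearly interpolated
onto a 101-point FPR grid, averaged, and banded with mean ± t·(bootstrap SE
of the mean TPR), resampling tests with replacement.

The label-permutation negative control permutes diet labels **within each
cohort** (cross-LODO conditions on the cohort structure, so the blocked
permutation is the exchangeable null) and **redraws the permutation for
each CV repetition**. A single global permutation would let its chance
correlation with the features propagate into every fold of the experiment:
at desk scale (three cohorts of 400, ~12 vegans each) that inflates the
spread of the experiment's mean AUC to roughly ±0.07, whereas averaging
over independent per-repetition permutations estimates the null mean
itself. Even so, with ~36 minority-class samples in total the null mean
carries an irreducible spread of about ±0.03 across experiment seeds — an
information floor of the desk-scale design, worth remembering when reading
single-run control values.

Presence-from-FFQ prediction models features whose within-cohort prevalence
lies in [0.10, 0.90]; the per-cohort AUC standard error is the SD of
per-fold AUCs over √(number of tests) (floored at 1e-4 to keep pooling
weights finite when folds agree exactly), and cohort AUCs pool through the
same DerSimonian–Laird estimator.

## hPDI scoring

Quintile boundaries are the 20/40/60/80th percentiles of the scored
population's group intakes, computed per cohort by default (each cohort's
own distribution defines its quintiles) with a pooled option. Ties at a
boundary score into the lower bin — a fixed, documented convention.
Interior bins score 2/3/4 in order; the extremes (5 above the top cutpoint
for positive groups, 1 below the bottom; reversed for reverse groups) pin
the mapping. The 18-group composition and the positive/reverse flags are
instrument-specific and therefore **data** (they arrive with the FFQ group
map); fewer than 18 mapped groups is a configuration error unless an
n-group variant is explicitly requested. Samples with any unresolvable
group intake are flagged, never silently scored.

## Food overlap

The food-SGB call is inclusive (detected in ≥ 4 food samples at the
catalog's 0.1% detection threshold); the signature rule is strict
(prevalence > 0.001 as a fraction) — both encoded exactly as their
definitions read, and the call is monotone in both thresholds. Monte-Carlo
chi-squared replicates are drawn under fixed margins (the conditional
null), `p = (1 + #{χ²* ≥ χ²})/(n_mc + 1)` with 99,999 replicates by
default. Health-rank comparisons run Levene's test first and report the
equal-variance two-sample t-test on the ranks of two signature sets;
unranked features are dropped with a logged count. The "most common food
SGBs" selection for prevalence testing uses overall prevalence, with
per-diet counts reported.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: five cohorts
of unequal size by default (1062/12353/7931/118/97 — desk-scale runs pass
smaller sizes), diet proportions 0.92/0.05/0.03, 300 sparse compositional
features, log-normal feature means (SD 2.0 across features), a per-cohort ×
feature random shift (SD 0.3) creating between-cohort structure, Bernoulli
zero-inflation with per-feature prevalence drawn uniformly from
[0.10, 0.95], and closure to 100 per sample. Covariates: age ~ N(50, 12²)
clipped to [18, 95], BMI ~ N(25, 4²) clipped to [15, 60], sex Bernoulli(½).

Effects are planted on the arcsin-sqrt scale: the target SMD becomes a
shift of the transformed value of one group's nonzero entries (positive
effects raise the comparison group; negative effects raise the reference
group instead, since near-zero abundances cannot be pushed lower), followed
by re-closure. An empirical calibration loop then measures the realized
Cohen's d over the diet pair and rescales the shift until it matches the
target — but only when both diet groups have ≥ 10 samples: with smaller
groups the realized d is dominated by sampling noise rather than
attenuation, and "calibrating" against it would chase noise, so tiny-group
cohorts keep the analytic first-pass shift (unbiased for the target). The
truth record stores, per planted feature and cohort, the target SMD, the
final shift and the realized d, so tests can assert against what was
actually planted. Signature features are kept at prevalence 0.90 so
abundance effects dominate over presence effects.

FFQ intakes are log-normal per item with diet-dependent shifts (healthy
plant groups up for vegetarians/vegans, less-healthy plant groups down),
hard zeros for excluded foods (meat and fish for vegetarians and vegans;
additionally dairy, eggs and animal fat for vegans), and couplings to
designated food features: presence of a food feature raises its category's
item intakes, plus a continuous term in the feature's standardized
transformed abundance. Health ranks are uniform on [0, 1] except planted
signature features, centered at 0.38 (comparison-enriched) or 0.53
(reference-enriched) with SD 0.08 — separations of the size the rank
comparison is meant to detect.

One global seed fans out through `SeedSequence(seed, spawn_key=...)`:
cohort i draws from spawn key (i,), feature-level parameters from a fixed
high key, so adding a cohort never perturbs existing ones and identical
seeds reproduce every table byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no phylogenetic correlation among features (the
UniFrac path is exercised on explicit toy trees instead), no
compositionally induced negative correlation beyond closure, no sequencing
depth or batch effects, no strain-level structure, and feature–FFQ
couplings far cleaner than real dietary measurement error. Tests
demonstrate that the estimators recover what was planted under the study's
sampling structure, not that real diet effects are of any particular size.

## Problem sizes used in tests and the acceptance run

The shared test fixture uses 3 cohorts × 300 samples × 100 features; the
acceptance-grade experiments use 3 × 400 × 200 with 10 planted features
(the classification scale) and 3 × 500 × 200 over 50 replicates (parameter
recovery). These sizes keep every experiment's Monte-Carlo error within the
asserted margins while the whole suite stays in the minutes range on one
CPU — the package's chosen desk-scale envelope.

## Known limitations

- Only DerSimonian–Laird heterogeneity is implemented (no REML or
  Hartung–Knapp); that is the estimator the workflow is defined around.
- Zero-inflated mixed models for food-SGB counts/cumulative abundance are
  out of scope; group contrasts go through the Dunn-test path.
- The linear mixed model for richness with cohort random effects is out of
  scope; richness is compared per cohort via Kruskal–Wallis/Dunn.
- PERMANOVA permutations are free (no restricted blocks), matching the
  default behavior of the standard distance-based implementations.
- Aitchison zeros use a multiplicative pseudocount (half the smallest
  nonzero proportion, configurable); results at very high sparsity are
  sensitive to that choice, as with any CLR-based distance.
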