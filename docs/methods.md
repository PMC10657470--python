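# Methods

This note documents the statistical machinery in `gutapns`: the models
and the assumptions they inherit, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Study design assumptions

The package targets a specific design: a small trauma-survivor cohort
(tens of subjects) in which each subject contributes **one** stool
metagenome, profiled to species relative abundances (percent scale)
and taxon-stratified pathway abundances, plus neuropsychiatric
outcomes measured at weeks 2, 8 and 12 after trauma. Pairing one
microbiome sample with three outcome timepoints rests on the
assumption that the adult gut microbiome is stable over a few months
in the absence of major perturbation; the longitudinal structure is
then in the outcomes, not the microbiome, and all models treat the
subject as the unit of clustering (a random intercept). Nothing in the
code precludes other week sets — the week labels are parameters — but
the train/test protocol (below) presumes at least two early weeks and
one late week.

Abundances are held on the percent scale on disk (matching profiler
output) and converted to proportions internally. The
variance-stabilizing arcsine-square-root transform asin(√p) is applied
wherever abundance enters a linear model; forests receive raw
proportions, since trees are invariant to monotone transforms.

## Instrument scoring

* **PCL-5**: sum of 20 items each scored 0–4 (range 0–80). Positive
  PTSD screen at raw score **> 31**; the cut is strict-greater because
  the downstream group split is "≤ 31 vs > 31", and it is exposed as a
  parameter.
* **PROMIS Depression 8b**: consumed directly as a t-score (population
  mean 50, SD 10). Positive screen at **t ≥ 60**, one SD above the
  population mean.
* **Somatic symptoms**: count of 12 yes/no post-concussive items
  (range 0–12).

## Per-species screen and variance partition

Tier 1 fits, for each species independently,

    y_it = β0 + age_i·β1 + sex_i·β2 + bmi_i·β3 + race_i·β4
         + days_since_trauma_i·β5 + week_t + γ_s·asin√(p_is)
         + b_i + ε_it,    b_i ~ N(0, σ_b²),  ε ~ N(0, σ_e²)

by REML (statsmodels `MixedLM`), with week as a categorical fixed
effect and days from trauma to stool collection as a continuous
covariate. The Wald p-value of the abundance term enters one
Benjamini–Hochberg correction across all species (BH is the field
default when only "FDR corrected" is specified); selection is q ≤
0.05. Zero-variance species and singular or non-converged fits are
*flagged and assigned p = 1* rather than dropped, so the BH family
size m does not depend on fit pathologies.

Tier 2 refits a single mixed model containing every selected species
plus the covariates. Collinear (aliased) species columns are dropped
left-to-right with a warning. With zero selected species the result is
an explicit "no model" object, not an exception.

**Variance partition.** Shares are sequential (Type I) ANOVA sums of
squares: terms enter in model order — covariates, week, then species —
and each term's SS is the drop in residual SS when its columns join
the design. Sequential SS are computed by OLS projection of the
outcome onto the nested designs; this makes the decomposition exact
(term SS plus residual SS equals total SS, so shares sum to one by
construction) and entering covariates first makes the species share
conservative. Two normalizations are reported: the default divides by
*total* SS (fixed + residual), so "microbiome share 0.48" reads as 48%
of total outcome variation; a fixed-effects-only normalization is also
computed, since published pie-chart shares are ambiguous between the
two. Coefficients and p-values still come from the mixed model; only
the SS bookkeeping uses OLS projections.

## Mixed-effect random forest

The MERF model is y_ij = f(x_ij) + b_i + ε_ij with a regression forest
for f and a scalar random intercept per subject (no random slopes: the
repeated measures are two early-week outcomes per subject, too few to
identify slope variance). Fitting alternates, EM-style:

1. forest fit on de-biased responses y_ij − b_i;
2. BLUP of each intercept, b_i = σ_b²·1ᵀV_i⁻¹(y_i − f(X_i)) with
   V_i = σ_b²·11ᵀ + σ_e²·I, evaluated in closed form via the rank-one
   structure (b_i = σ_b²·Σ r_ij / (σ_e² + n_i σ_b²));
3. standard EM variance updates
   σ_e² ← N⁻¹ Σ_i [εᵢᵀεᵢ + σ_e²(n_i − σ_e² tr V_i⁻¹)],
   σ_b² ← q⁻¹ Σ_i [b_i² + σ_b²(1 − σ_b²·1ᵀV_i⁻¹1)];
4. the generalized log-likelihood
   GLL = Σ_i [εᵢᵀεᵢ/σ_e² + b_i²/σ_b² + n_i·log σ_e² + log σ_b²]
   (up to constants, lower is better) is recorded; iteration stops
   when its relative change falls below `tol` or at `max_iter`.

Defaults: 300 trees, max_features = ⌈p/3⌉ (the classical regression
heuristic), min_samples_leaf = 3, max_iter = 50, tol = 1e-4. These are
standard desk-scale settings; all are constructor arguments. On
realistic cohort sizes the GLL often keeps drifting slightly at
tol = 1e-4 and the fit stops at the iteration cap with
`converged=False`; the variance components are stable well before
that. In the σ_b² = 0 limit the intercept penalty and log σ_b² terms
are omitted from the GLL (documented degenerate case). Forest OOB
error plays no role in convergence.

Prediction adds the fitted intercept for clusters seen in training and
uses the forest alone for unseen clusters. A `base_learner` hook
accepts any sklearn-style regressor in place of the forest; with a
linear learner on linear data the EM loop reproduces REML variance
components within a few percent, which the test suite uses as an
independent cross-check against `statsmodels.MixedLM`.

Caveat on in-sample variance components: a forest partially memorizes
residual noise, so fitted σ_e² is biased downward and σ_b² absorbs any
subject-level signal the forest misses. Recovery to within a factor of
two is the realistic expectation at n ≈ 50 subjects, and predictive
claims should rest on the held-out evaluation, not the trace.

## Evaluation protocol and permuted importance

`time_split` partitions outcome rows by week: weeks 2 and 8 train,
week 12 tests — a true partition by construction, and subjects missing
a week simply contribute fewer rows. The pipeline is repeated over ten
forest seeds (defaults 0–9); per seed it records test RMSE and Pearson
correlation of true versus predicted week-12 values.

Permuted importance is computed **on the held-out week-12 rows**: for
each feature, the mean increase in test MSE over 5 independent column
permutations, with the fitted cluster intercepts held fixed so only
the forest's use of the feature is measured. Constant features score
exactly 0. Cross-seed aggregation averages importances per feature
(over the seeds where a fit succeeded), drops non-positive means,
ranks descending with lexicographic tie-breaks, and reports the top
15. Each reported feature carries a direction: the Spearman rank
correlation of its values with the outcome across all observation
rows (each subject's single microbiome sample paired with each of that
subject's outcome observations). Pearson measures model fit; Spearman
gives the sign, being the convention for monotone microbiome–outcome
association.

## Pathway contribution tables

For a pathway with taxon-stratified rows, a sample's taxon fraction is
that taxon's stratified abundance over the sample's total stratified
abundance, pooled at genus or species rank (species tables refine
genus tables exactly). Samples with zero stratified total are
uninformative and become NA. Group summaries (groups default to the
week-12 diagnosis split, the headline outcome week) are the **mean of
per-sample fractions**, renormalized to sum to 100% and printed with
two decimals. Mean-of-fractions weights every sample equally; the
alternative pooled-abundance mode (sum group abundances, then take
fractions), which lets high-biomass samples dominate, is implemented
and selectable, as group summaries of compositional data have no
single canonical convention.

## Power analysis

Power for a one-sample Spearman correlation test uses the Fisher-z
approximation — atanh(r) treated as N(atanh(ρ), 1/(n−3)) — applied to
Spearman as classical power packages do:

    power = Φ(√(n−3)·atanh(ρ) − z_{1−α/2}) + Φ(−√(n−3)·atanh(ρ) − z_{1−α/2})

two-sided, α = 0.05 by default. At ρ = 0.5, n = 51 this gives 0.9675
(0.97 to two decimals). The Monte Carlo mode is the ground truth for
the approximation: it draws bivariate-normal samples calibrated so the
*population Spearman* equals ρ (Pearson r = 2·sin(πρ/6)) and counts
rejections of `scipy.stats.spearmanr` at α; at ρ = 0.5, n = 51 it
agrees with the closed form to within about 0.01. `minimum_n` inverts
the closed form by bisection. Note an exact-threshold subtlety: the
closed-form power at n = 51 is 0.9675, so against a target of
literally 0.97 the minimal n is 52; n = 51 is minimal for the
unrounded value.

## Synthetic cohorts

The generator produces the data structure the analysis assumes, with
known truth:

* **Species table** — per-subject log-normal intensities around fixed
  per-species base levels (SD 1.5, giving a realistic abundance
  hierarchy), log-noise SD 2 for overdispersion; per sample, the
  intensities below the 25% detection quantile are zeroed (sparsity),
  and the remainder is closed to sum exactly 100. Defaults: 51
  subjects, 200 species.
* **Planted effects** — 5 effector species (base level boosted by 2
  log units so they stay prevalent) with coefficients γ = (2.0, 0.5,
  0.5, 0.5, 0.5) on *z-scored* arcsine-sqrt abundance, one clearly
  dominant so rank-recovery checks are well defined. Effect sizes are
  chosen for testability of the pipeline, not to mimic any measured
  microbiome–outcome effect.
* **Latent response** — r_it = covariatesᵀβ + Σ_s γ_s z_si +
  slope·week + b_i + ε_it with σ_b = 2, σ_e = 1 (intraclass
  correlation 0.8), a mild −0.05/week recovery slope, and small
  covariate effects (0.01/year age, 0.5 male, 0.02/unit BMI).
* **Instruments** — one latent response mapped three ways: PCL-5 =
  clip(round(30 + 5r), 0, 80); PROMIS t = 50 + 3r (pure affine, hence
  the workhorse for calibration tests); somatic ~ Binomial(12,
  logistic(0.4r − 0.3)), Binomial-12 because the somatic instrument is
  12 binary items.
* **Pathways** — stratum abundance = fixed weight × species abundance,
  community totals the exact stratum sums, plus UNMAPPED/UNINTEGRATED
  bookkeeping rows; the default spec wires each arginine-set pathway
  to one effector plus abundant bystanders.
* **Covariates** — age ~ N(50, 15) clipped to 18–85, ~51% female, BMI
  ~ N(29, 6), race/ethnicity at (0.61, 0.25, 0.02, 0.12), days from
  trauma to stool collection log-normal with median 45 and range
  clipped to 5–182.

One `numpy.random.default_rng(seed)` drives everything; a fixed seed
reproduces a cohort bit-for-bit.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: phylogenetic correlation among
species, batch and extraction effects, true within-subject microbiome
drift, item-level instrument noise, informative dropout, and
measured-confounder structure beyond the three covariates. Tests on
these cohorts validate the *machinery* (estimation, selection,
ranking, calibration under the stated model), not biological effect
sizes.

## Numerical conventions and edge cases

* Retention percentages round half-up to one decimal (74/106 → 69.8).
* Table invariants: abundances ≥ 0; per-sample species sums ≤ 100 +
  1e-6; stratified sums ≤ community totals + 1e-6; violations raise at
  parse time. Writers emit full float precision, so read∘write is an
  exact identity.
* Proportions are accepted within 1e-12 slop outside [0, 1] (float
  dust from closure) and clipped before the arcsine transform.
* σ_e² is floored at 1e-12 and σ_b² at 0 during EM; BH q-values are
  monotone in p by construction.
* Ties in importance ranking break lexicographically by feature name;
  ties in Spearman use average ranks.
* Degenerate inputs have defined outcomes rather than exceptions where
  a run should continue: per-seed fit failures are recorded in the
  seed's result; empty diagnosis groups are omitted with a warning;
  zero selected species yields the explicit no-model result.

## Problem sizes used in the validation suite

The statistical checks run at the default study conditions (51
subjects × 3 weeks, 200 species): dominant-effector recovery over ten
seeds, null-screen calibration and variance-share monotonicity over 20
replicate cohorts each, and the OLS-limit and REML cross-checks at
300 subjects / 100 clusters where asymptotic agreement is the claim.
Unit tests of plumbing use smaller cohorts (12–30 species) since they
assert contracts, not statistics.
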