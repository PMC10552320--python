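# Methods

## Scope and model

The package implements a serum cfDNA methylation biomarker pipeline for
colorectal screening as three linked statistical procedures, plus the
synthetic-data generator used to exercise them end to end.

**Differential methylation.** Pool-level beta values (methylation
fractions in [0, 1]) are modelled per CpG as a linear model
`beta ~ class (+ covariates)` fitted by ordinary least squares. Pools
are independent measurements, so OLS is the generalized-least-squares
special case that applies; no correlation structure is modelled. The
effect of interest is Δβ, the AN-minus-NN difference of group means on
the beta scale. Working on the beta scale (rather than M-values) keeps
effects in the units the downstream filters use; a logit transform is
available for sensitivity analysis via the covariate/QC layer. Residual
variances are moderated by an empirical-Bayes hierarchical model in
which true variances follow a scaled inverse chi-square with prior df
d₀ and location s₀². The prior is estimated by moment matching on
log s²: the excess variance of `log s² − digamma(d/2) + log(d/2)` over
the sampling term `trigamma(d/2)` is inverted through the trigamma
function to give d₀ (Newton iteration), and the mean gives s₀². The
moderated statistic uses the posterior variance
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)` and a t reference with d + d₀ df.
Benjamini–Hochberg step-up q-values control the FDR; DMPs are calls at
q ≤ 0.10 (configurable), with direction = sign(Δβ).

Probe QC removes positions with any missing value ("failed positions")
and positions whose within-group residuals fail a Shapiro–Wilk
normality screen at α = 0.01. The screen's α is a config knob: 0.01
trades a ~1% loss of well-behaved probes against reliable removal of
heavy-tailed ones (a t(1)-residual probe at n = 28 is caught ≥80% of
the time in simulation).

**Prioritization.** The SES-style search performs forward conditional
inclusion over DMP features using likelihood-ratio chi-square tests
between nested logistic models. A candidate's score is its *maximal*
p-value over conditioning subsets of the selected set (up to `max_k`),
so a feature must be associated both marginally and conditionally —
the max-min association heuristic of constraint-based selection.
Inclusion additionally requires clearing a per-step Bonferroni guard
(α divided by the number of candidates tested at that step); without
it, the minimum of ~hundreds of null p-values clears α in most runs
and pure-noise features enter. A backward pass prunes features whose
conditional association decays. At each inclusion the competitors
whose same-size models differ from the winner's by less than the
chi-square(1) critical value — and which are themselves significant —
are recorded as an equivalence class; the signature set is the
cartesian product of the classes (capped, default 256). Perfectly
separated logistic fits fall back to a ridge-penalized fit and are
logged, never fatal.

In the orchestrated pipeline, the signature list is topped up with
singleton signatures for the strongest DMPs (by |Δβ|) not covered by
any SES signature before ranking, so the ranked list always has enough
probes for the top-15 draw even when the search returns few
equivalence classes.

Signatures are ranked by repeated stratified k-fold misclassification
(default 5-fold × 10 repeats) under three learners: logistic
regression, random forest (500 trees) and a linear SVM — all with
pinned seeds. A probe inherits the minimum error over (signature,
learner) pairs containing it, and probes are ordered lexicographically
by (error ascending, |Δβ| descending, q ascending). Candidates are the
top 15 plus up to 3 probes with 0% cross-validated error on the
NN-vs-AA subproblem plus the externally concordant set (|bisulfite
difference| > 0.30 with matching sign), deduplicated with first
provenance kept — 26 in the default layout.

**Panels and validation.** Candidate pyrosequencing percents (raw or
log10(x+1); the +1 offset maps the frequent 0% readings to 0), age and
a sex indicator are standardized and offered to LASSO / elastic-net
logistic regression. The penalty path is log-spaced over three decades
below the smallest all-zero λ; λ* minimizes the mean cross-validation
error over stratified folds (default 10). The CV loss is
**misclassification error**, with ties at the minimum resolved toward
the larger penalty (the sparser model); binomial deviance is available
by config. This choice is deliberate: at evaluation-cohort size
(n ≈ 48) the min-deviance λ virtually always admits extra noise
features, whereas min-class-error with sparse tie-breaking recovers a
planted 2-marker support exactly in ≥80% of replicates, matching the
sparse panels the procedure is meant to produce.

Validation panels are refit by maximum-likelihood logistic regression
(IRLS). Separation (non-convergence or |coef| > 20) triggers a
bias-reduced Firth fit — the hat-diagonal score correction — which is
flagged on the results object. Diagnostics: leave-one-out
cross-validated probabilities pooled into a single empirical ROC; AUC
as the Mann–Whitney statistic with half-weight ties (equal to the
trapezoid rule); a DeLong placement-value 95% CI; the Youden cutoff
t* = argmax(sens + spec − 1) with ties broken toward higher
specificity; confusion metrics with exact Clopper–Pearson 95% CIs
(this convention reproduces a printed 100 (91–100)% specificity for
39/39 and 78.8 (67–88)% sensitivity for 52/66 exactly); detection
rates by adenoma location and tumor stage with a two-sided Fisher
distal-vs-proximal comparison; Wilcoxon rank-sum (exact for group
sizes ≤ 25 without ties, tie-corrected normal otherwise) and
signed-rank (zeros dropped) group tests; and application of the frozen
panel + cutoff to off-target (non-colorectal) tumor sera.

## The synthetic generator

The generator defines the study conditions the tests run under.

- **Cohort**: 433 subjects in the study's three-cohort composition
  (discovery 280 = 130 NN + 150 AN; evaluation 48; validation 105 =
  39 NN + 23 distal-AA + 19 proximal-AA + 24 CRC), ages uniform on
  [50, 75], four hospitals, sexes balanced within (cohort,
  pathological-group) strata so pooling is feasible by construction.
- **Methylomes**: per-probe baselines drawn from a bimodal mixture
  (array-like beta-value landscape), individual betas ~
  Beta(mφ, (1−m)φ) with precision φ = 50 (between-subject SD ≈ 0.07
  at mid-range). Planted DMPs shift the AN group mean by a signed Δβ
  (default magnitudes 0.10–0.30, 86.7% hypermethylated); baselines of
  planted probes are redrawn so shifted means stay inside (0, 1).
- **Pools**: unweighted means of the 10 member betas (equal cfDNA
  mass), perturbed on the logit scale with SD 0.10 and clipped. The
  scale is calibrated to two stated properties: pool values track
  member means at r > 0.95 across probes, and pooled-array vs
  individual-pyrosequencing concordance stays above the r ≥ 0.6 bound.
  No deeper moment of pooled-cfDNA array noise is claimed.
- **Pyrosequencing**: percent = 100·β + Gaussian noise (SD 8
  percentage points), clipped to [0, 100].
- **External bisulfite table**: exactly `n_concordant` planted CpGs
  (default 8) exceed the 0.30 difference threshold with the matching
  sign; all other rows are sub-threshold so a sign-flipped table
  yields zero concordant markers.
- **Off-target tumors and pairs**: 16 non-CRC tumor sera drawn from
  the NN-like marker distribution except a contaminated fraction
  (default 3/16) drawn at the AN-like means; 8 serum/plasma pairs with
  a zero-centered plasma offset (SD 1 percentage point).

Default problem sizes are desk-scale by design: 20,000 probes with 200
planted DMPs for epigenome-wide runs (the probe count is a config
knob, not a constant), chosen so the full pipeline and its calibration
simulations complete in minutes on a single core.

What passing tests do and do not show: the generator produces
independent, beta-distributed probes with exchangeable subjects; it
does not emulate probe cross-hybridization, cell-composition shifts,
batch structure beyond slide randomization, spatial correlation along
the genome, or bisulfite-conversion chemistry. Calibration results
(e.g. the empirical FDR of the caller) therefore validate the
statistical machinery under its own assumptions, not the behavior of
EPIC arrays on real pooled sera.

## Numerical and design choices

- **Pool construction**: within each pathological group, each sex is
  sorted by age and dealt round-robin across the group's pools. This
  makes pools *mutually* age-matched — a between-pool ANOVA on age
  stays null when members come from one age distribution, the property
  the design reports. (Chunking consecutive age-sorted subjects, the
  obvious alternative, maximizes between-pool age differences and
  fails that ANOVA.)
- **Slide allocation**: groups placed from most to least frequent,
  each pool going to the admissible slide (no group repeats) with most
  free capacity; the default slide count accommodates both total
  volume and the most frequent group. Infeasible layouts (more pools
  of one group than slides) raise an error.
- **Stratified splits**: proportional allocation with
  largest-remainder rounding per stratum; exact target totals; the
  split sizes (48/105) are explicit inputs, not derived from a
  percentage.
- **Recovery-scenario construction**: the planted-2-of-26 lasso
  scenario uses effects of 0.26–0.34 beta (~30 percentage points, the
  magnitude the external concordance filter treats as large). Support
  recovery requires each informative marker to be predictive but not
  individually sufficient; weaker effects let noise features into the
  CV-optimal model and stronger ones let a single marker reach zero CV
  error.
- **Degenerate inputs**: all-zero residual variances abort moderation;
  empty DMP sets propagate as empty tables, not errors; undefined
  confusion metrics (empty denominators) are reported as missing, not
  NaN; all-tied group tests return p = 1 with a warning.
- **Determinism**: every stochastic step takes an explicit seed; the
  pipeline derives per-stage substream seeds from the master seed by a
  32-bit FNV hash, so stages can be rerun independently and a rerun of
  the same config is bit-identical.

## Known limitations

- LOOCV scores of a near-constant panel are dominated by the
  leave-one-out class-prevalence shift and anti-correlate with the
  left-out label (pooled AUC ≤ 0.5); this is a property of pooled
  LOOCV scoring, not a bug, and is documented in the tests.
- The SES implementation covers the forward–backward search with
  equivalence enumeration only; it is not a re-implementation of every
  option of published constraint-based selection packages.
- IDAT parsing, array normalization, probe cross-hybridization QC and
  read-level bisulfite processing are out of scope; the pipeline
  consumes beta matrices and tabular differentials.
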