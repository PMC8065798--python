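# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Multiple correspondence analysis

The analysis operates on a patients × variables table of category labels with
no missing cells (missing data are rejected, not imputed; any imputation is a
documented pre-step for the caller). Every observed level of every variable is
expanded into an indicator column — including both levels of binary variables,
since the method's output is a clustering of *category levels* and "Yes" and
"No" levels must both be placeable points. A variable with a single observed
level has zero variance, would produce a zero-mass complement column, and is
rejected by name.

With X the I × J indicator matrix, K variables, N = ΣX, P = X/N, masses
r = P1 and c = P′1, the fitted decomposition is the SVD of the standardized
residuals S = D_r^{-1/2}(P − rc′)D_c^{-1/2}. Principal coordinates are
F = D_r^{-1/2}UΔ and G = D_c^{-1/2}QΔ. Implementation details:

* **Trivial axes** with singular value ≤ 1e-12 are dropped; an exactly
  independent table therefore yields zero retained dimensions.
* **Sign convention:** each axis is oriented so that its largest-magnitude
  column loading is positive. SVD backends are free to flip axis signs; the
  convention makes coordinates reproducible across platforms.
* **Bases:** the indicator matrix is the default analysis basis; the Burt
  matrix X′X is available. The two are linked by λ_burt = λ_indicator², a
  relation asserted in the tests. Category coordinates from the indicator
  basis feed the clustering stage.
* **Inertia:** total inertia is ‖S‖²_F, equal to the sum of eigenvalues and,
  on the indicator basis, to the closed form J/K − 1. Per-point inertias are
  mass-weighted squared coordinate norms over the retained axes, so column
  point inertias sum to the retained eigenvalue total; on all axes they equal
  the per-column Pearson chi-squared contributions.
* **Dimension choice:** smallest d whose cumulative inertia share reaches a
  threshold (default 0.80). The threshold is a genuinely open choice; 0.80 is
  a conventional middle ground, configurable, and `rule="all"` disables the
  truncation. No Benzécri/Greenacre inertia correction is applied.

## K-means with v-fold cross-validation

Lloyd iteration with initial centers drawn uniformly from the *distinct*
points, nearest-center assignment by Euclidean distance (ties to the lowest
cluster index, for determinism), mean updates, and termination when
assignments stabilize or after `max_iter` sweeps. The within-cluster sum of
squares is asserted non-increasing across iterations. An emptied cluster is
repaired by moving in the point farthest from its assigned center, never
emptying a donor cluster. The returned solution is the best of `n_restarts`
seeded restarts by within-cost.

The *clustering cost* reported for a solution is the mean Euclidean
**distance** of points to their assigned centers by default; the mean
**squared** distance (within-cluster mean sum of squares) is a config option.
Distance is the cost the selection rule compares; the iteration itself is
standard k-means in both cases.

Cross-validation splits the category points into v = 5 folds by one seeded
shuffle, reused across every k so that D̄_k values are comparable. Each fold's
cost is the mean distance of held-out points to the nearest center trained on
the complement; D̄_k averages the folds. Selection rules:

* `cost_plateau` (default): scan k upward, stop at the first k with
  |D̄_{k+1} − D̄_k| < 0.01. The 0.01 tolerance is an absolute threshold on the
  cost scale of MCA principal coordinates.
* `fold_significance`: smallest k whose per-fold costs are not significantly
  better at k+1 under a paired two-sided t-test at α = 0.05. The original
  description of this comparison names no test; the paired t-test on the five
  fold costs is this package's interpretation, recorded here.

If no k in range satisfies the rule, the global-minimum-cost k is returned
with an explicit warning flag in the selection trace — on unstructured data
the plateau may simply never occur within k ≤ 10.

Category points, not patients, are clustered by default (`G`); clustering `F`
is possible by passing row coordinates. Outcome variables are *active* in the
MCA — their levels are meant to appear among the clustered points, which is
how outcome/risk-factor co-membership is read off.

## Logistic control arm

Per-variable Rao score tests (the statistic for one categorical covariate
entering the intercept-only model; 1 df for binary, J−1 df otherwise; equal to
the Pearson chi-squared for a binary covariate) and a multiple logistic
regression fit by IRLS. Convergence is declared when the relative
log-likelihood change falls below 1e-8, capped at 100 iterations. Two
safeguards keep the iteration finite-valued without changing where it
plateaus: each update step is capped at ±10 per coefficient (under separation
the weighted least-squares system is numerically singular and a raw solve can
jump arbitrarily far along a divergent direction) and is halved while it
decreases the log-likelihood. Dummy coding uses "No" as the reference where
present, otherwise the lexicographically first level, reproducing the
conventional "Yes vs No", "Male vs Female", "30–39 vs 20–29", "CCI=1 vs CCI=0"
contrasts. Each outcome's model excludes the other outcome from the
covariates by default (configurable).

There is deliberately **no penalized or bias-reduced fit by default**: the
arm exists to exhibit the rare-event failure (|β| drifting past 10, Wald SEs
in the thousands, odds ratios collapsing to 0) honestly. Every term with
|β| > 10 or SE > 50 carries a separation flag, and the diagnostics list the
zero-count outcome cells that cause it.

## Cohort filter

ICD-9-CM matching is dot-insensitive prefix matching; a trailing `X` is a
wildcard, and range patterns (e.g. `296.2X–296.3X`, `571.0–571.3`) expand to
explicit prefix lists at load time, where malformed patterns fail immediately.
The packaged registry carries the case-defining sets (lung cancer, depression,
anxiety) and the baseline exclusion sets (depression, anxiety, bipolar,
alcohol-induced disorders).

Eligibility: first lung-cancer-coded visit (the index visit) inside
2001-01-01..2007-12-31, age 20–39 at index (floor of the year difference),
no baseline-exclusion code during 2001, and optional censoring (death or
withdrawal) excludes the patient. An outcome is coded "Yes" when at least
`min_confirmations` (default 3) matching diagnoses fall on *distinct dates
strictly after* the index date. "Consecutive" confirmations are read as "at
least three, any spacing" by default since no maximum gap is defined for the
referral-confirmation sequence; `max_gap_days` optionally requires the run to
have bounded gaps. Every input patient lands in exactly one of cohort or
exclusion log, with one reason per excluded patient; patients without a
birthdate are logged as unresolvable. Comorbidity covariates are accepted as
precomputed columns (their defining code lists are not part of the registry
and remain caller-supplied config).

Note one overlap inherited from the code definitions themselves: `300.4` is
both a depression code and inside the anxiety set's `300.XX`; the filter
applies each set independently and does not de-overlap them.

## Synthetic data

The generator emulates the study conditions: 1022 patients, sixteen
categorical variables with the published marginal frequencies (e.g. 520 male,
25 depression cases, 2 heart-failure carriers). Variables outside any planted
block get **exact level counts** by largest-remainder rounding and a seeded
permutation, so fixture column totals are reproducible integers. Planted
blocks tie member levels through a shared latent Bernoulli whose rate is the
rarest member's marginal: with probability `strength` a member copies the
latent state, otherwise it draws from its marginal. Strength 0 is exact
independence, strength 1 is deterministic co-occurrence, and the pairwise
odds ratio is increasing in between. Member marginals are preserved only
approximately for strength > 0 (pulled toward the rarest member's rate) — the
source study gives no joint distribution to match, so no exact-joint
calibration is attempted or claimed.

Presets: `table1` (no blocks), `table1_planted` (three two-member blocks
among levels with prevalence ≥ 2%, default strength 0.95 — the recovery
benchmark), and `table1_anxiety_osteoporosis` (the single qualitative pattern
the clustering stage should surface). Claims scenarios generate long-format
visit streams: `lung_cancer_followup` round-trips a generated cohort through
the filter (index visits start in 2002 so confirmations never intersect the
2001 baseline-exclusion window), `toy_filter` is a five-patient
hand-enumerable fixture, `empty` is the degenerate case. Blob point sets for
the cluster-count experiments place k centers on a circle with a fixed
minimum separation (default 6.0) and isotropic noise (default sd 0.02), sized
so that consecutive-k cost differences beyond the true k fall below the 0.01
plateau tolerance while differences before it stay far above.

**What passing does and does not show.** The synthetic cohorts reproduce the
marginal frequencies and planted low-order associations only; real claims
cohorts have correlated comorbidities, secular trends, censoring and coding
noise that the generator does not model. Recovery of planted structure
validates the machinery (embedding, cost, selection), not the substantive
claim that any particular real-world risk factor clusters with any outcome.

## Problem sizes and runtime choices

Tests and the acceptance script run at the study's own scale where that is
cheap (1022 × 16 cohorts; 33 category points; k scanned 2–10 with v = 5), and
at enumerable scale where an exhaustive oracle is the point (≤ 8 points for
partition enumeration, ≤ 50 rows for the eigendecomposition cross-check).
Planted-recovery experiments use 10–20 seeds per setting; the full suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The plateau rule depends on an absolute tolerance (0.01); on data whose
  coordinate scale differs greatly from MCA principal coordinates it may
  need adjustment, and on structureless data it falls back (flagged) to the
  global cost minimum.
* Lloyd k-means guarantees only local optima; exactness is asserted at
  enumerable sizes, and restarts make larger instances reliable but not
  certified.
* The latent-Bernoulli block mechanism cannot plant associations between
  levels of the same variable, a variable cannot belong to two blocks, and
  block-member marginals shift with strength.
* Wald p-values accompany flagged coefficients for completeness but are
  meaningless under separation — that is the pathology being exhibited, not
  an oversight.
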