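# Methods

`alscourse` reimplements, as a tested pipeline, a disease-course
analysis for amyotrophic lateral sclerosis (ALS) clinical-trial
cohorts: per-subject parametric trajectory fitting, information-
criterion model selection, unsupervised derivation of binary
functional-decline and death-risk classes, survival analysis of those
classes, and machine-learning prediction of the classes from baseline
and trajectory features.  Because pooled ALS trial databases are
registration restricted, every stage is exercised on a synthetic
cohort generator with full ground truth.

## Trajectory models

Each subject's series of a clinical variable (visit day `t`, value
`y`) is summarised by one of four decline curves:

| family       | value at day `t`   | parameters |
|--------------|--------------------|------------|
| linear       | `A − k·t`          | A, k       |
| exponential  | `A·exp(−k·t)`      | A, k       |
| harmonic     | `A / (1 + k·t)`    | A, k       |
| Weibull      | `A·exp(−(k·t)^b)`  | A, k, b    |

`A` is the model-estimated baseline (day 0) value in the variable's
own units; `k` is the per-day progression rate, positive for decline
in every family; `b` is the Weibull shape.  The families share the
baseline identity (value `A` at `t = 0`) and the Weibull nests the
exponential at `b = 1`.  For growing variables (`k < 0`) the Weibull
power is evaluated as the odd extension `sign(k·t)·|k·t|^b`, which
keeps growth representable in all four families and makes the `b = 1`
identity exact rather than approximate.

Constraints: `k ∈ [−5, 5]` per day; `b ∈ [0.0001, 5]`; `A ∈ [0, 53]`
for the ALSFRS-R total score and `[0, 2·max(y)]` otherwise.  The 53
bound is the field convention even though the instrument maximum is
48; it deliberately leaves head room for noisy baselines.  In
practice fitted ALS rates land in `0–1`/day (typically `10⁻⁴–10⁻²`);
the wide `k` interval only bounds the search.

### Fitting

The error model is Gaussian with a common SD per series; profiling the
SD analytically reduces the negative log-likelihood to the sum of
squared errors, so the likelihood optimum is the least-squares
optimum.  The optimiser is bounded simulated annealing (geometric
cooling, Gaussian proposals with SD 5% of each bound width,
temperature rescaled by the starting SSE so the schedule is
unit-invariant) whose best state is then polished by bounded
trust-region least squares.  The polish supplies the final precision,
so the annealing pass only has to select the right basin and the
default schedule is deliberately short (T₀ = 1, cooling 0.85, 20
steps per temperature, T_min = 0.01, one restart).  A long pure-
annealing schedule reaches the same optima but costs ~20× more per
series, which matters at cohort scale (~20,000 series fits per run);
the cheap schedule + polish is validated against an exhaustive
200×200(×20) grid-search oracle to within 0.1% SSE in the test suite.
Each series gets a deterministic seed derived by hashing
(seed, subject, variable), so cohort fits are reproducible and
independent of iteration order.

Series with fewer distinct visit days than `arity + 1` are not fitted;
they carry the earliest observed value as a baseline-only feature
(`A` without `k`), and are excluded from rate-based stages.

### Weibull collapse

A fitted shape within `eps = 10⁻³` of its bounds (0.0001 or 5) — or of
1, where the Weibull is exactly exponential — is collapsed: the series
is refitted with the exponential family and that fit is used.  The
tight `eps` follows the boundary-collapse convention; note that under
realistic noise the fitted shape hovers near but rarely within `10⁻³`
of 1, so the collapse mainly fires on near-noiseless or boundary
cases.

## Model comparison

Per subject the four fits are ranked in ascending order of AICc and of
RMSE.  The AICc uses the Gaussian-profile form

    AICc = n·ln(SSE/n) + 2p + 2p(p+1)/(n − p − 1)

with `p` counting curve parameters only (the profiled error SD is
common to all families and cancels).  Fits with `n ≤ p + 1` are
excluded.  Two conventional tie rules flag statistically
indistinguishable fits: an absolute AICc gap below 2, and a runner-up
RMSE within 10% of the best.  Equal scores break by fewer parameters,
then fixed family order (linear, exponential, harmonic, Weibull).  The
cohort census credits ties to the top-ranked family.

Two regime observations, verified in the tests and worth keeping in
mind when reading cohort censuses:

* The small-sample AICc correction dominates the Weibull's
  overfitting gain only for short series (~8 visits, where the third
  parameter costs ~7 AICc units).  At 11+ visits the Weibull's SSE
  gain on exponential-truth noise beats the penalty for roughly a
  fifth of subjects.
* Raw RMSE cannot penalise complexity at all: a fully optimised
  Weibull strictly nests the exponential, so by RMSE it wins whenever
  the `b ≈ 1` collapse does not fire.  An exponential RMSE majority
  therefore only appears when curvature is strong relative to noise.
  Published exponential-majority RMSE censuses on real data are, by
  the same argument, most plausibly a sign of incompletely converged
  three-parameter fits or frequent boundary collapse.

Downstream stages use the exponential fit for every subject
regardless of the per-subject winner; the census is reporting only.

## Stratification

**Decline classes.**  The fitted ALSFRS-R total-score rates `k` are
clustered by k-means (k-means++ initialisation, 25 restarts, fixed
seed) and by PAM (partitioning around medoids, BUILD + SWAP,
deterministic; implemented here as no installed package provides PAM).
Average silhouette width over k = 2…5 confirms a binary split.  Both
methods run at two clusters; the method with the larger between-
cluster gap in median `|k|` is retained, and the cluster with the
larger median `|k|` is labelled *fast*.  Clustering is on raw `k`,
not `|k|`.

**Death-risk classes.**  Days from trial start to death — or to last
follow-up contact when no death is recorded, a proxy that understates
survival — are clustered by binary k-means.  The cluster with the
smaller centre is *high risk*; the reported class boundary is the
midpoint of the two cluster centres (the boundary definition is a
package choice; any value between the extreme cluster members
reproduces the same labels).  The PAM SWAP step is O(k·n²) on the
pairwise-distance matrix and is intended for cohort-scale inputs
(≲ 5,000 subjects).

## Survival analysis

The fast/slow class is related to survival by univariate Cox
proportional-hazards regression (slow as reference, Efron tie
handling, subjects without a recorded death right-censored at last
follow-up) and by Kaplan-Meier curves per class.  Monotone-likelihood
failures are refitted with a light ridge penalty and flagged.

## Prediction experiments

Five experiments mirror the study design (see the table in
`alscourse.predict`): decline class from trajectory features (A and k),
decline class and continuous ALSFRS-R rate from baseline-only
features (A), and death-risk class from trajectory or baseline-only
features.  ALSFRS-R item scores are excluded as features except in the
baseline survival experiment; the ALSFRS-R total is excluded from the
decline experiments entirely because the decline label is a
deterministic function of its fitted rate — admitting it would leak
the label.

Learners: RUSBoost (authored here — AdaBoost.M1 whose every round
first randomly undersamples the majority class to the minority count;
the per-round balance is asserted), AdaBoost, random forest, Gaussian
naive Bayes, and a single decision tree, each behind a median-
imputation step fitted on the training fold only.  Default
hyperparameters: 100 boosting rounds, depth-3 base trees, learning
rate 0.5, 500 forest trees.  Validation is a stratified 60/40
train/test split repeated 100 times (20 in desk-scale runs; the mean
AUC is stable at that depth while a full run stays available via the
`n_repeats` argument).  Classification reports mean ± SD ROC AUC and a
row-normalised confusion matrix at the 0.5 operating point; regression
reports RMSE normalised by the observed label range (nRMSE, %).

Variable importance is permutation importance on held-out folds
averaged over repeats (deterministic name tie-break); the reduced-
model search scans top-N prefixes of the ranking and returns the
smallest N whose mean AUC is within 0.01 (or nRMSE within 1 point) of
the full model, flagging the case where no prefix qualifies.  These
tolerances are declared, not estimated.

## Synthetic cohort generator

The generator emulates the *structure* of pooled ALS trial databases:

* ~10-month visit schedules (nominal days 0, 30, …, 300; Gaussian
  day jitter SD 3), visits stopping at death;
* a latent fast/slow progressor split (21% fast) with ALSFRS-R decline
  rates 0.004/day vs 0.0005/day from a baseline near 39.4 — a ~20 vs
  ~3 point six-month drop;
* a latent high/low death-risk class correlated with the decline class
  (P(high|fast) = 0.63, P(high|slow) = 0.45, ~49% high overall);
* log-normal death times with medians 150 days (high risk) and 433
  days (low risk), fast progressors dying earlier within their risk
  class (×0.55 vs ×1.05) — jointly yielding a fast-vs-slow hazard
  ratio near 4;
* ~53% of subjects with the death day withheld, plus an administrative
  export cutoff at day 750 beyond which deaths are never recorded;
  last contact days are log-normal (median 400, σ 0.25) across pooled
  trials with 1–2-year horizons, truncated below death;
* class-linked decline-rate signal in weight, albumin, alkaline
  phosphatase and creatine kinase; risk-linked rate signal in total
  bilirubin, gamma glutamyltransferase, bicarbonate, chloride and
  pulse, with baseline shifts in bilirubin, gamma glutamyltransferase,
  urine specific gravity and the stair-climbing item; blood pressures
  and filler variables carry no class signal;
* 10% of measurement cells missing at random (the day-0 ALSFRS-R
  total always observed, anchoring every subject).

Noise SDs per variable are set to plausible assay/measurement scales
(e.g. 1.5 ALSFRS-R points, 1.2 kg weight) — the source study reports
none, so they are calibrated only to reproduce the qualitative class
separations, not any printed accuracy.  Values are truncated at zero
(score floors) rather than rejection-sampled.

What the generator does **not** emulate: trial-specific batch effects,
study-duration heterogeneity beyond the follow-up distribution,
synonym/unit chaos of real exports, non-Gaussian assay noise, and
informative missingness.  Passing tests on synthetic cohorts therefore
demonstrate the pipeline's correctness and internal consistency, not
real-data accuracy; published real-data AUCs are not reproducible
without the restricted database.

## Data cleaning

Raw long-format records are cleaned by the conventional rules: drop
records with missing days or non-numeric values ("ambiguous" entries
are operationalised as unparseable or outside configurable physical
ranges); average duplicated (subject, variable, day) measurements;
merge synonymous variable headings (overlaps averaged under the
duplicate rule, with a warning); and back-calculate summed-instrument
cells — a missing total from complete items, or a single missing item
from the total — discarding derived items outside their valid range.
No other imputation is performed, and the chain is idempotent.

## Numerical choices and degenerate inputs

* Harmonic fits restrict `k > (10⁻⁶ − 1)/t_max` so the denominator
  stays positive on the observation window; evaluation outside the
  domain raises.
* Exponent arguments are clipped at ±150 during optimisation so
  absurd proposals score astronomically bad SSE instead of
  overflowing.
* SSE is floored at 10⁻¹² inside logs; a perfect fit yields a large
  negative AICc rather than −∞.
* Degenerate clustering inputs (all-equal values) raise; subjects
  with neither death day nor follow-up day are excluded and logged.
* All randomness flows from explicit integer seeds; reruns are
  byte-identical.

## Problem sizes

Desk-scale defaults — 600-subject cohorts, 20 holdout repeats, 200
Monte-Carlo subjects for recovery checks, 20 toy series for the
optimiser oracle — were chosen so a complete analysis runs in minutes
on one CPU while leaving every statistical conclusion stable under the
fixed seeds; the full 100-repeat protocol is a parameter away.
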