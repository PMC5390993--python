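# alscourse

Disease-course modelling and prognosis prediction for amyotrophic
lateral sclerosis (ALS) clinical-trial cohorts.

ALS progresses at wildly different speeds between patients, which
makes trials long and large.  Given pooled trial records — longitudinal
measurements of the revised ALS functional rating scale (ALSFRS-R),
vital signs and laboratory panels, plus survival follow-up —
`alscourse` answers the questions a trialist asks when designing
enrichment or stratification strategies:

1. **How fast is each patient declining?**  Every subject's series of
   every variable is fitted to parametric decline curves (linear,
   exponential, harmonic, Weibull) by bounded simulated annealing with
   least-squares polish; the exponential form `y(t) = A·e^(−k·t)`
   (baseline `A`, per-day rate `k`) summarises each trajectory after a
   small-sample AICc / RMSE census across families.
2. **Are there discrete progression phenotypes?**  k-means and PAM
   clustering of the fitted ALSFRS-R rates yields binary *fast/slow
   progressor* classes; clustering days-to-death (with last follow-up
   as a proxy when death is unrecorded) yields binary *high/low death
   risk* classes, related to the decline classes by univariate Cox
   regression and Kaplan-Meier curves.
3. **Can the classes be predicted?**  Five repeated-holdout (60/40,
   stratified, 100 repeats) experiments predict the classes and the
   continuous rate from trajectory and/or baseline features using
   RUSBoost (implemented here), AdaBoost, random forest, naive Bayes
   and decision trees, with permutation-importance ranking and a
   minimal-sufficient-feature search.

Real pooled ALS databases are registration restricted, so the package
ships a synthetic cohort generator (`alscourse.synthetic`) that
emulates their structure — irregular ~10-month visit schedules, latent
progression and death-risk classes, log-normal death times, ~53%
unrecorded deaths, missing cells — with full ground truth, making
every pipeline stage testable end to end.

## Worked example

```python
from alscourse import CohortConfig, generate_cohort, run_study

visits, statics, outcomes, truth = generate_cohort(
    CohortConfig(n_subjects=300, seed=11)
)
result = run_study(visits, statics, outcomes, seed=5, n_repeats=10)
print(result.summary())
```

```
Study summary
=============
Best-fit family census (fraction of subjects):
              aicc   rmse
linear       0.498  0.143
exponential  0.091  0.009
harmonic     0.359  0.091
weibull      0.052  0.758
Decline classes (kmeans): 17.0% fast
Survival classes: threshold 277 days, 57.3% high risk
Cox PH (fast vs slow), n=45+219, events=126
  HR = 3.104 (95% CI 1.925-5.003), p = 3.33e-06
decline_trajectory: mean AUC = 0.963 (SD 0.011) [rusboost]
decline_baseline: mean AUC = 0.497 (SD 0.073) [rusboost]
k_baseline: mean nRMSE% = 24.076 (SD 2.370) [random_forest]
survival_trajectory: mean AUC = 0.884 (SD 0.025) [adaboost]
survival_baseline: mean AUC = 0.689 (SD 0.031) [adaboost]
```

Reading it: subjects split ~17/83 into fast/slow progressors from
their fitted ALSFRS-R rates, and fast progressors carry a ~3× death
hazard.  The survival boundary falls at ~277 days.  Decline class is
predicted almost perfectly from post-baseline *trajectories* (AUC
0.96) but is unpredictable from *baseline* values alone (AUC ≈ 0.5) —
the qualitative signature of this analysis — while death risk is
predictable from both, better from trajectories.  The family census
shows why a single family is used downstream: near-flat slow decliners
are ambiguous between families (and the raw-RMSE column always favours
the nesting Weibull), so the census is reporting, not gating.

Single-series fitting is available statsmodels-style:

```python
from alscourse import TrajectoryModel
fit = TrajectoryModel(t_days, scores, family="exponential",
                      a_bounds=(0, 53)).fit(seed=0)
print(fit.summary())   # A, k, SSE/RMSE/AICc
```

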