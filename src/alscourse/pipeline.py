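"""End-to-end cohort analysis: fit, select, stratify, predict.

`fit_cohort` fits every subject's series (all four families for the
ALSFRS-R total, which feeds the model-selection census; the exponential
family for everything else, which supplies the A/k features), and
`run_study` chains stratification, survival analysis and the five
prediction experiments.  This is the programmatic equivalent of the
full study and is what the acceptance script drives.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import predict as P
from . import selection, stratify, survival
from .synthetic import ALSFRS_TOTAL, statics_wide
from .trajectory import (
    ALSFRS_TOTAL_A_MAX,
    AnnealConfig,
    ModelFamily,
    fit_all,
    fit_model,
)

__all__ = ["fit_cohort", "CohortFitResult", "run_study", "StudyResult"]


@dataclass(frozen=True)
class CohortFitResult:
    """Exponential A/k per (subject, variable) plus the family census."""

    fits: pd.DataFrame  # subject_id, variable, A, k, n_points, converged
    comparisons: list  # ModelComparison for the census variable
    census: pd.DataFrame  # fraction best-fit per family (aicc/rmse columns)


def fit_cohort(visits: pd.DataFrame, census_variable=ALSFRS_TOTAL,
               config: AnnealConfig | None = None, seed=0) -> CohortFitResult:
    """Fit trajectories for every (subject, variable) series.

    The census variable is fitted with all four families and ranked;
    its exponential fit also provides the subject's decline rate.  All
    other variables get the exponential fit only.  Deterministic given
    ``seed``; per-series seeds are derived by hashing, so results do
    not depend on iteration order.
    """
    import zlib

    config = config or AnnealConfig()
    rows, comparisons = [], []
    groups = visits.groupby(["subject_id", "variable"], sort=True)
    for (sid, var), grp in groups:
        t = grp["day"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        child = zlib.crc32(f"{seed}:{sid}:{var}".encode()) % (2**31 - 1)
        a_bounds = (0.0, ALSFRS_TOTAL_A_MAX) if var == census_variable else None
        if var == census_variable:
            fits = fit_all(t, y, a_bounds=a_bounds, config=config, seed=child,
                           subject_id=sid, variable=var)
            comparisons.append(selection.rank_models(fits.values()))
            fit = fits[ModelFamily.EXPONENTIAL]
        else:
            fit = fit_model(t, y, ModelFamily.EXPONENTIAL, a_bounds=a_bounds,
                            config=config, seed=child, subject_id=sid, variable=var)
        rows.append(
            {
                "subject_id": sid,
                "variable": var,
                "A": fit.A,
                "k": fit.k,
                "n_points": fit.n_points,
                "converged": fit.converged,
            }
        )
    fits_df = pd.DataFrame(rows)
    ranked = [c for c in comparisons if c.aicc_ranking]
    census = selection.best_fit_census(ranked) if ranked else None
    return CohortFitResult(fits=fits_df, comparisons=comparisons, census=census)


@dataclass(frozen=True)
class StudyResult:
    """Everything the end-to-end study computes on one cohort."""

    cohort_fit: CohortFitResult
    decline: stratify.DeclineClassAssignment
    survival_classes: stratify.SurvivalClassResult
    cox: survival.CoxResult
    crosstab_counts: pd.DataFrame
    crosstab_pct: pd.DataFrame
    experiments: dict  # Experiment -> CVResult

    def summary(self) -> str:
        lines = ["Study summary", "=" * 13]
        if self.cohort_fit.census is not None:
            lines.append("Best-fit family census (fraction of subjects):")
            lines.append(self.cohort_fit.census.round(3).to_string())
        lines.append(
            f"Decline classes ({self.decline.method}): "
            f"{self.decline.fast_fraction:.1%} fast"
        )
        lines.append(
            f"Survival classes: threshold {self.survival_classes.threshold_days:.0f} "
            f"days, {self.survival_classes.high_risk_fraction:.1%} high risk"
        )
        lines.append(self.cox.summary())
        for exp, res in self.experiments.items():
            metric = "AUC" if res.mode == "classify" else "nRMSE%"
            lines.append(
                f"{exp.value}: mean {metric} = {res.mean_score:.3f} "
                f"(SD {res.sd_score:.3f}) [{res.spec.algorithm}]"
            )
        return "\n".join(lines)


#: Study-reported winning learner per experiment.
DEFAULT_LEARNERS = {
    P.Experiment.DECLINE_TRAJECTORY: P.LearnerSpec("rusboost", "classify"),
    P.Experiment.DECLINE_BASELINE: P.LearnerSpec("rusboost", "classify"),
    P.Experiment.K_BASELINE: P.LearnerSpec("random_forest", "regress"),
    P.Experiment.SURVIVAL_TRAJECTORY: P.LearnerSpec("adaboost", "classify"),
    P.Experiment.SURVIVAL_BASELINE: P.LearnerSpec("adaboost", "classify"),
}


def run_study(visits, statics, outcomes, seed=0, n_repeats=20,
              anneal_config=None, learners=None,
              cohort_fit: CohortFitResult | None = None) -> StudyResult:
    """Run the complete analysis on one cohort.

    ``n_repeats`` controls the repeated-holdout count per experiment
    (the full protocol uses 100; 20 keeps a desk-scale run fast while
    leaving the mean AUC stable).  A precomputed ``cohort_fit`` may be
    supplied to skip refitting.
    """
    learners = {**DEFAULT_LEARNERS, **(learners or {})}
    if cohort_fit is None:
        cohort_fit = fit_cohort(visits, config=anneal_config, seed=seed)
    fits = cohort_fit.fits

    k_total = (
        fits[(fits["variable"] == ALSFRS_TOTAL) & fits["k"].notna()]
        .set_index("subject_id")["k"]
    )
    decline = stratify.derive_decline_classes(k_total, seed=seed)

    surv_outcomes = stratify.derive_survival_outcomes(outcomes)
    survival_classes = stratify.derive_survival_classes(surv_outcomes, seed=seed)
    risk = survival_classes.outcomes.set_index("subject_id")["risk_class"]

    cox = survival.cox_univariate(surv_outcomes, decline.labels)
    counts, pct = stratify.cross_tabulate(decline.labels, risk)

    statics_w = statics_wide(statics)
    label_sets = {
        P.Experiment.DECLINE_TRAJECTORY: (decline.labels, "fast"),
        P.Experiment.DECLINE_BASELINE: (decline.labels, "fast"),
        P.Experiment.K_BASELINE: (k_total, None),
        P.Experiment.SURVIVAL_TRAJECTORY: (risk, "high"),
        P.Experiment.SURVIVAL_BASELINE: (risk, "high"),
    }
    experiments = {}
    for exp, spec in learners.items():
        labels, positive = label_sets[exp]
        table = P.build_feature_table(fits, statics_w, labels, exp)
        experiments[exp] = P.repeated_holdout(
            table.X, table.y, spec, n_repeats=n_repeats, seed=seed,
            positive=positive,
        )
    return StudyResult(
        cohort_fit=cohort_fit,
        decline=decline,
        survival_classes=survival_classes,
        cox=cox,
        crosstab_counts=counts,
        crosstab_pct=pct,
        experiments=experiments,
    )
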