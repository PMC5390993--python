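"""Information-criterion comparison of the candidate decline curves.

Each subject's four family fits are ranked in ascending order of AICc
(small-sample-corrected Akaike criterion, Gaussian-profile form) and of
RMSE.  Two fits are treated as statistically indistinguishable when the
top pair differs by less than 2 AICc units, or when the runner-up RMSE
exceeds the best by less than 10% of the best — the conventional
rules of thumb.  A cohort-level census of winning families is used to
justify carrying a single family (in practice the exponential) through
the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .trajectory import FAMILY_ORDER, ModelFamily, TrajectoryFit

__all__ = ["aicc", "ModelComparison", "rank_models", "best_fit_census",
           "AICC_TIE_DELTA", "RMSE_TIE_FRACTION"]

#: An absolute AICc difference below this is an insignificant gap.
AICC_TIE_DELTA = 2.0
#: A runner-up RMSE within this fraction of the best is an insignificant gap.
RMSE_TIE_FRACTION = 0.10

_FAMILY_RANK = {f: i for i, f in enumerate(FAMILY_ORDER)}


def aicc(sse: float, n: int, p: int) -> float:
    """Small-sample Akaike criterion for a Gaussian least-squares fit.

    ``n * ln(sse/n) + 2p + 2p(p+1)/(n - p - 1)`` with ``p`` counting
    curve parameters only (the profiled error SD is common to all
    families and cancels in comparisons).

    Raises
    ------
    ValueError
        If ``n <= p + 1`` (the correction term is undefined); such
        fits are excluded from ranking.
    """
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} <= p+1={p + 1}")
    return n * math.log(max(sse, 1e-12) / n) + 2 * p + (2 * p * (p + 1)) / (n - p - 1)


@dataclass(frozen=True)
class ModelComparison:
    """Per-subject ranking of family fits by AICc and by RMSE."""

    subject_id: object
    variable: str | None
    aicc_ranking: tuple  # families, best first
    rmse_ranking: tuple
    aicc_tie: bool
    rmse_tie: bool
    chosen: ModelFamily | None
    excluded: tuple = field(default_factory=tuple)

    @property
    def best_by_aicc(self):
        return self.aicc_ranking[0] if self.aicc_ranking else None

    @property
    def best_by_rmse(self):
        return self.rmse_ranking[0] if self.rmse_ranking else None


def _sort_key(fit: TrajectoryFit, score: float):
    # deterministic tie-break: score, then fewer parameters, then family order
    return (score, fit.family.arity, _FAMILY_RANK[fit.family])


def rank_models(fits, subject_id=None, variable=None) -> ModelComparison:
    """Rank a subject's fits ascending by AICc and RMSE with tie flags.

    Fits that did not converge, or whose point count is too small for
    the AICc correction, are excluded (reported in ``excluded``).  With
    fewer than two valid fits both tie flags are False.
    """
    fits = list(fits)
    if fits:
        subject_id = subject_id if subject_id is not None else fits[0].subject_id
        variable = variable if variable is not None else fits[0].variable
    valid, excluded = [], []
    for f in fits:
        if f.converged and f.aicc is not None:
            valid.append(f)
        else:
            excluded.append(f.family)

    by_aicc = sorted(valid, key=lambda f: _sort_key(f, f.aicc))
    by_rmse = sorted(valid, key=lambda f: _sort_key(f, f.rmse))

    aicc_tie = rmse_tie = False
    if len(valid) >= 2:
        aicc_tie = abs(by_aicc[0].aicc - by_aicc[1].aicc) < AICC_TIE_DELTA
        r1, r2 = by_rmse[0].rmse, by_rmse[1].rmse
        rmse_tie = (r2 - r1) < RMSE_TIE_FRACTION * r1 if r1 > 0 else r2 == r1

    return ModelComparison(
        subject_id=subject_id,
        variable=variable,
        aicc_ranking=tuple(f.family for f in by_aicc),
        rmse_ranking=tuple(f.family for f in by_rmse),
        aicc_tie=aicc_tie,
        rmse_tie=rmse_tie,
        chosen=by_aicc[0].family if by_aicc else None,
        excluded=tuple(excluded),
    )


def best_fit_census(comparisons) -> pd.DataFrame:
    """Fraction of subjects won by each family, per criterion.

    Ties are credited to the top-ranked model, so fractions sum to 1
    within each criterion.  Returns a DataFrame indexed by family name
    with columns ``aicc`` and ``rmse``.
    """
    comparisons = [c for c in comparisons if c.aicc_ranking]
    if not comparisons:
        raise ValueError("no comparisons with a ranked fit")
    names = [f.value for f in FAMILY_ORDER]
    out = pd.DataFrame(0.0, index=names, columns=["aicc", "rmse"])
    for c in comparisons:
        out.loc[c.best_by_aicc.value, "aicc"] += 1
        out.loc[c.best_by_rmse.value, "rmse"] += 1
    return out / len(comparisons)
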