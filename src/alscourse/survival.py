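"""Association between decline class and survival.

Univariate Cox proportional-hazards regression of days-to-death on the
binary fast/slow progressor class (slow as the reference level, Efron
tie handling), plus Kaplan-Meier product-limit curves per class.
Subjects without a recorded death day are right-censored at their last
follow-up contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

__all__ = ["CoxResult", "cox_univariate", "km_curves"]


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit of survival on decline class (fast vs slow)."""

    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_fast: int
    n_slow: int
    n_events: int
    flagged: bool = False  # monotone likelihood / separation suspected
    message: str = ""

    def summary(self) -> str:
        flag = "  [FLAGGED: unstable estimate]" if self.flagged else ""
        return (
            f"Cox PH (fast vs slow), n={self.n_fast}+{self.n_slow}, "
            f"events={self.n_events}\n"
            f"  HR = {self.hazard_ratio:.3f} "
            f"(95% CI {self.ci_lower:.3f}-{self.ci_upper:.3f}), "
            f"p = {self.p_value:.3g}{flag}"
        )


def _assemble(outcomes: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    df = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    df = df[["days", "event_observed"]].join(
        classes.rename("decline_class"), how="inner"
    )
    return df.dropna(subset=["decline_class"])


def cox_univariate(outcomes: pd.DataFrame, classes: pd.Series) -> CoxResult:
    """Hazard ratio of death for fast vs slow progressors.

    Parameters
    ----------
    outcomes : DataFrame with ``subject_id``/index, ``days`` and
        ``event_observed`` columns.
    classes : Series of "fast"/"slow" indexed by subject id; subjects
        missing a class are excluded.
    """
    df = _assemble(outcomes, classes)
    n_fast = int((df["decline_class"] == "fast").sum())
    n_slow = int((df["decline_class"] == "slow").sum())
    if n_fast == 0 or n_slow == 0:
        raise ValueError("both decline classes must be present")
    n_events = int(df["event_observed"].sum())
    if n_events == 0:
        raise ValueError("no observed deaths: Cox model is undefined")

    model_df = pd.DataFrame(
        {
            "days": df["days"].astype(float),
            "event": df["event_observed"].astype(int),
            "fast": (df["decline_class"] == "fast").astype(int),
        }
    )
    cph = CoxPHFitter()
    flagged, message = False, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(model_df, duration_col="days", event_col="event")
        except ConvergenceError as err:
            # monotone likelihood: refit with light ridge and flag
            flagged, message = True, f"penalised refit after: {err}"
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(model_df, duration_col="days", event_col="event")
    s = cph.summary.loc["fast"]
    hr = float(np.exp(s["coef"]))
    if not np.isfinite(s["se(coef)"]) or s["se(coef)"] > 10:
        flagged, message = True, message or "very large standard error"
    # clamp the CI exponent: a separated fit can report +/-inf bounds
    return CoxResult(
        hazard_ratio=hr,
        ci_lower=float(np.exp(max(s["coef lower 95%"], -700.0))),
        ci_upper=float(np.exp(min(s["coef upper 95%"], 700.0))),
        p_value=float(s["p"]),
        n_fast=n_fast,
        n_slow=n_slow,
        n_events=n_events,
        flagged=flagged,
        message=message,
    )


def km_curves(outcomes: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier survival curves per decline class.

    Returns a long DataFrame (class, time, survival, at_risk); the
    product-limit estimate is right-censored at unobserved deaths.
    """
    df = _assemble(outcomes, classes)
    frames = []
    for cls, grp in df.groupby("decline_class", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["days"], event_observed=grp["event_observed"].astype(int))
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
        frames.append(
            pd.DataFrame(
                {
                    "decline_class": cls,
                    "time": surv.index.to_numpy(dtype=float),
                    "survival": surv.to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
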