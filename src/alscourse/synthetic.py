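"""Synthetic ALS trial cohorts with known ground truth.

Pooled-trial databases of ALS clinical records are registration
restricted, so the pipeline is exercised on simulated cohorts that
reproduce their *structure*: long-format visit records over roughly
ten-month studies at irregular visit days, a latent fast/slow
progressor split (about 21% fast), class-dependent exponential decline
of the ALSFRS-R and of a panel of laboratory/vital-sign variables,
log-normal death times correlated with a latent death-risk class, and
roughly half of the subjects with the death day withheld (the last
follow-up day is then all that survives into the outcome table).

Every subject carries a full ground truth (latent classes, true curve
parameters, true death day) so that downstream recovery can be scored
exactly.

Default calibration
-------------------
Fast progressors lose ~20 ALSFRS-R points over six months
(``k = 0.004``/day from a baseline near 40) and slow progressors ~3
points (``k = 0.0005``/day).  Death times are log-normal with medians
near 150 days (high-risk) and 433 days (low-risk).  Demographics match
a pooled-trial population: age 56.2 (SD 11.8), 40% female, 64% limb
onset, 65% on riluzole.  Decline-class signal is planted in the decline
rates of weight, albumin, alkaline phosphatase and creatine kinase;
death-risk signal in the rates of total bilirubin, gamma
glutamyltransferase, bicarbonate, chloride and pulse, with baseline
shifts in bilirubin, gamma glutamyltransferase, urine specific gravity
and the stair-climbing ALSFRS-R item.  Inert filler variables stress
variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .trajectory import model_value

__all__ = [
    "ConfigError",
    "VariableSpec",
    "CohortConfig",
    "GroundTruth",
    "default_variable_specs",
    "plant_trajectory",
    "generate_cohort",
    "write_cohort",
    "statics_wide",
]

ALSFRS_TOTAL = "alsfrs_r_total"
ALSFRS_ITEMS = tuple(f"alsfrs_r_q{i}" for i in range(1, 13))
#: Stair-climbing is item 9 of the revised functional rating scale.
ALSFRS_CLIMBING_STAIRS = "alsfrs_r_q9"


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


@dataclass(frozen=True)
class VariableSpec:
    """Generating distribution for one clinical variable.

    ``a_mean`` and ``k_mean`` are either scalars or dicts keyed by
    latent class — ``{"fast": .., "slow": ..}`` ties the parameter to
    the decline class, ``{"high": .., "low": ..}`` to the death-risk
    class.  ``k_sd`` may likewise be a dict.  Values are truncated at
    ``floor`` (score floors / physical zero) and at ``cap`` if given.
    """

    family: str = "exponential"
    a_mean: float | Mapping = 40.0
    a_sd: float = 5.0
    k_mean: float | Mapping = 0.0005
    k_sd: float | Mapping = 0.0002
    noise_sd: float = 1.0
    b: float | None = None
    floor: float = 0.0
    cap: float | None = None

    def _resolve(self, value, decline_class, risk_class):
        if isinstance(value, Mapping):
            key = decline_class if "fast" in value else risk_class
            return value[key]
        return value

    def draw_params(self, decline_class, risk_class, rng):
        a = rng.normal(self._resolve(self.a_mean, decline_class, risk_class), self.a_sd)
        k = rng.normal(
            self._resolve(self.k_mean, decline_class, risk_class),
            self._resolve(self.k_sd, decline_class, risk_class),
        )
        return max(a, self.floor), k


def default_variable_specs() -> dict:
    """Default panel: ALSFRS-R total + 12 items, labs, vitals, fillers."""
    specs = {
        ALSFRS_TOTAL: VariableSpec(
            a_mean=39.4, a_sd=5.28,
            k_mean={"fast": 0.004, "slow": 0.0005},
            k_sd={"fast": 0.0008, "slow": 0.00015},
            noise_sd=1.5, cap=48.0,
        ),
        "weight": VariableSpec(
            a_mean={"fast": 72.0, "slow": 76.0}, a_sd=18.3,
            k_mean={"fast": 0.0009, "slow": 0.0002},
            k_sd={"fast": 0.0003, "slow": 0.0001},
            noise_sd=1.2,
        ),
        "albumin": VariableSpec(
            a_mean=4.3, a_sd=0.3,
            k_mean={"fast": 0.0006, "slow": -0.0002},
            k_sd={"fast": 0.0002, "slow": 0.0001},
            noise_sd=0.15,
        ),
        "alkaline_phosphatase": VariableSpec(
            a_mean=80.0, a_sd=20.0,
            k_mean={"fast": -0.0012, "slow": -0.0001},
            k_sd={"fast": 0.0004, "slow": 0.0002},
            noise_sd=6.0,
        ),
        "creatine_kinase": VariableSpec(
            a_mean={"fast": 180.0, "slow": 220.0}, a_sd=90.0,
            k_mean={"fast": 0.0015, "slow": 0.0002},
            k_sd={"fast": 0.0005, "slow": 0.0002},
            noise_sd=15.0,
        ),
        "bilirubin_total": VariableSpec(
            a_mean={"high": 0.55, "low": 0.65}, a_sd=0.18,
            k_mean={"high": -0.0010, "low": 0.0002},
            k_sd={"high": 0.0004, "low": 0.0002},
            noise_sd=0.05,
        ),
        "gamma_glutamyltransferase": VariableSpec(
            a_mean={"high": 45.0, "low": 35.0}, a_sd=18.0,
            k_mean={"high": -0.0012, "low": -0.0001},
            k_sd={"high": 0.0004, "low": 0.0002},
            noise_sd=4.0,
        ),
        "bicarbonate": VariableSpec(
            a_mean={"high": 27.0, "low": 25.5}, a_sd=2.2,
            k_mean={"high": -0.0008, "low": -0.0001},
            k_sd={"high": 0.0003, "low": 0.0001},
            noise_sd=0.8,
        ),
        "chloride": VariableSpec(
            a_mean={"high": 101.0, "low": 102.5}, a_sd=2.5,
            k_mean={"high": 0.0004, "low": 0.00005},
            k_sd={"high": 0.00015, "low": 0.00005},
            noise_sd=1.0,
        ),
        "pulse": VariableSpec(
            a_mean={"high": 80.0, "low": 75.0}, a_sd=10.0,
            k_mean={"high": -0.0006, "low": -0.0001},
            k_sd={"high": 0.0002, "low": 0.0001},
            noise_sd=4.0,
        ),
        "bp_systolic": VariableSpec(a_mean=128.0, a_sd=14.0, k_mean=0.0001,
                                    k_sd=0.0001, noise_sd=6.0),
        "bp_diastolic": VariableSpec(a_mean=80.0, a_sd=9.0, k_mean=0.0001,
                                     k_sd=0.0001, noise_sd=4.0),
        "urine_specific_gravity": VariableSpec(
            a_mean={"high": 1.018, "low": 1.014}, a_sd=0.004,
            k_mean=0.0, k_sd=0.00002, noise_sd=0.003,
        ),
    }
    for item in ALSFRS_ITEMS:
        # stair climbing carries a baseline death-risk signal
        a_mean = {"high": 3.2, "low": 2.6} if item == ALSFRS_CLIMBING_STAIRS else 3.3
        specs[item] = VariableSpec(
            a_mean=a_mean, a_sd=0.6,
            k_mean={"fast": 0.004, "slow": 0.0005},
            k_sd={"fast": 0.0012, "slow": 0.0004},
            noise_sd=0.4, cap=4.0,
        )
    for j in range(1, 4):
        specs[f"filler_{j}"] = VariableSpec(
            a_mean=50.0, a_sd=10.0, k_mean=0.0002, k_sd=0.0003, noise_sd=3.0
        )
    return specs


@dataclass(frozen=True)
class CohortConfig:
    """Generating conditions for a synthetic pooled-trial cohort."""

    n_subjects: int = 600
    fraction_fast: float = 0.21
    visit_days: tuple = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270, 300)
    visit_jitter_sd: float = 3.0
    study_length: int = 309
    variable_specs: dict = field(default_factory=default_variable_specs)
    missing_rate: float = 0.10
    #: log-normal death-time medians (days) by latent risk class
    death_median_high: float = 150.0
    death_median_low: float = 433.0
    death_sigma_high: float = 0.55
    death_sigma_low: float = 0.30
    #: database-export cutoff: deaths after this day are not yet
    #: recorded, leaving only the last contact day
    vital_status_window: float = 750.0
    #: fast progressors die substantially earlier within their risk class
    fast_death_factor: float = 0.55
    slow_death_factor: float = 1.05
    #: latent risk-class mixing, calibrated to ~47% high risk overall
    p_high_given_fast: float = 0.63
    p_high_given_slow: float = 0.45
    followup_censor_rate: float = 0.53
    #: last-contact day for trial completers: log-normal across pooled
    #: trials with 1-2 year horizons (median 400 days)
    followup_median: float = 400.0
    followup_sigma: float = 0.25
    seed: int = 0

    def validate(self):
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        for name in ("fraction_fast", "missing_rate", "followup_censor_rate",
                     "p_high_given_fast", "p_high_given_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.visit_jitter_sd < 0:
            raise ConfigError("visit_jitter_sd must be >= 0")
        if not self.visit_days or min(self.visit_days) != 0:
            raise ConfigError("visit_days must start at day 0")
        if self.study_length <= 0:
            raise ConfigError("study_length must be positive")
        for var, spec in self.variable_specs.items():
            if spec.noise_sd < 0:
                raise ConfigError(f"variable_specs[{var}].noise_sd must be >= 0")
        total = self.variable_specs.get(ALSFRS_TOTAL)
        if total is not None and isinstance(total.k_mean, Mapping):
            if abs(total.k_mean["fast"]) <= abs(total.k_mean["slow"]):
                raise ConfigError(
                    "variable_specs[alsfrs_r_total].k_mean: |fast| must exceed |slow|"
                )
        return self

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        """Load a config from YAML; variable_specs entries are mappings."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "variable_specs" in raw:
            raw["variable_specs"] = {
                name: VariableSpec(**spec)
                for name, spec in raw["variable_specs"].items()
            }
        if "visit_days" in raw:
            raw["visit_days"] = tuple(raw["visit_days"])
        return cls(**raw).validate()


@dataclass(frozen=True)
class GroundTruth:
    """Latent state of a simulated cohort.

    ``subjects``: one row per subject — decline_class, risk_class,
    true_death_day (always present, even when censored), censored flag.
    ``params``: one row per (subject, variable) with the true curve
    parameters used for planting.
    """

    subjects: pd.DataFrame
    params: pd.DataFrame


def plant_trajectory(family, A, k, times, noise_sd, rng, b=None):
    """Curve values at ``times`` plus Gaussian noise, floored at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and nonnegative")
    clean = np.asarray(model_value(family, A, k, times, b), dtype=float)
    noisy = clean + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else clean
    return np.maximum(noisy, 0.0)


def _draw_statics(n, rng):
    age = rng.normal(56.2, 11.78, n).round(1)
    height = rng.normal(169.0, 9.94, n).round(1)
    female = (rng.random(n) < 0.401).astype(int)
    onset = rng.choice(["limb", "bulbar", "other"], size=n, p=[0.641, 0.191, 0.168])
    riluzole = (rng.random(n) < 0.653).astype(int)
    caucasian = (rng.random(n) < 0.566).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "height": height,
            "female": female,
            "onset_limb": (onset == "limb").astype(int),
            "onset_bulbar": (onset == "bulbar").astype(int),
            "riluzole": riluzole,
            "caucasian": caucasian,
        }
    )


def generate_cohort(config: CohortConfig | None = None):
    """Simulate a cohort; returns (visits, statics, outcomes, truth).

    * ``visits``: long format (subject_id, variable, day, value); visits
      stop at the true death day; cells are dropped independently at
      ``missing_rate`` except the day-0 ALSFRS-R total, which anchors
      every subject.
    * ``statics``: long format (subject_id, feature, value), numerically
      coded.
    * ``outcomes``: subject_id, death_day (NaN for the withheld
      fraction), last_followup_day.
    * ``truth``: :class:`GroundTruth`.

    Deterministic given ``config.seed``.
    """
    config = (config or CohortConfig()).validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subject_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    fast = rng.random(n) < config.fraction_fast
    decline_class = np.where(fast, "fast", "slow")
    p_high = np.where(fast, config.p_high_given_fast, config.p_high_given_slow)
    risk_class = np.where(rng.random(n) < p_high, "high", "low")

    med = np.where(risk_class == "high", config.death_median_high, config.death_median_low)
    sig = np.where(risk_class == "high", config.death_sigma_high, config.death_sigma_low)
    factor = np.where(fast, config.fast_death_factor, config.slow_death_factor)
    death_true = np.maximum(
        np.rint(med * factor * np.exp(sig * rng.standard_normal(n))), 1.0
    )

    censored = (rng.random(n) < config.followup_censor_rate) | (
        death_true > config.vital_status_window
    )
    fup_draw = config.followup_median * np.exp(
        config.followup_sigma * rng.standard_normal(n)
    )
    # follow-up contact cannot postdate death; subjects whose drawn
    # contact horizon exceeds their death day were last seen shortly
    # before dying
    last_fup = np.where(
        fup_draw < death_true,
        np.rint(fup_draw),
        np.maximum(np.rint(death_true * rng.uniform(0.85, 1.0, n)), 0.0),
    )
    death_day = np.where(censored, np.nan, death_true)

    statics = _draw_statics(n, rng)
    statics.insert(0, "subject_id", subject_ids)

    nominal = np.asarray(config.visit_days, dtype=float)
    variables = list(config.variable_specs)
    visit_rows = []
    param_rows = []
    for i, sid in enumerate(subject_ids):
        if config.visit_jitter_sd > 0:
            days = nominal + rng.normal(0.0, config.visit_jitter_sd, nominal.size)
            days[0] = max(days[0], 0.0)
        else:
            days = nominal.copy()
        days = np.rint(np.maximum(days, 0.0))
        days = np.unique(days)
        days = days[days < death_true[i]]
        if days.size == 0:
            days = np.array([0.0])
        for var in variables:
            spec = config.variable_specs[var]
            A, k = spec.draw_params(decline_class[i], risk_class[i], rng)
            values = plant_trajectory(spec.family, A, k, days, spec.noise_sd, rng, spec.b)
            if spec.cap is not None:
                values = np.minimum(values, spec.cap)
            keep = rng.random(days.size) >= config.missing_rate
            if var == ALSFRS_TOTAL:
                keep[0] = True  # anchor: baseline functional score always observed
            param_rows.append((sid, var, spec.family, A, k))
            for d, v, kp in zip(days, values, keep):
                if kp:
                    visit_rows.append((sid, var, int(d), float(v)))

    visits = pd.DataFrame(visit_rows, columns=["subject_id", "variable", "day", "value"])
    outcomes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "death_day": death_day,
            "last_followup_day": last_fup,
        }
    )
    truth = GroundTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "decline_class": decline_class,
                "risk_class": risk_class,
                "true_death_day": death_true,
                "censored": censored,
            }
        ),
        params=pd.DataFrame(
            param_rows, columns=["subject_id", "variable", "family", "A", "k"]
        ),
    )
    statics_long = statics.melt(
        id_vars="subject_id", var_name="feature", value_name="value"
    ).sort_values(["subject_id", "feature"], kind="stable").reset_index(drop=True)
    return visits, statics_long, outcomes, truth


def statics_wide(statics_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long static table to one numeric row per subject."""
    wide = statics_long.pivot(index="subject_id", columns="feature", values="value")
    return wide.astype(float)


def write_cohort(outdir, visits, statics, outcomes, truth: GroundTruth):
    """Write the four cohort tables as CSV files under ``outdir``."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visits.to_csv(outdir / "visits.csv", index=False)
    statics.to_csv(outdir / "statics.csv", index=False)
    outcomes.to_csv(outdir / "outcomes.csv", index=False)
    truth.subjects.merge(truth.params, on="subject_id").to_csv(
        outdir / "ground_truth.csv", index=False
    )
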