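"""Prognostic prediction experiments with repeated-holdout validation.

Five experiments are supported, mirroring the study design:

=====================  ======================================  ==========
experiment             features                                label
=====================  ======================================  ==========
decline_trajectory     A and k, all non-ALSFRS variables        fast/slow
decline_baseline       A only (+ statics)                       fast/slow
k_baseline             A only (+ statics)                       ALSFRS-R k
survival_trajectory    A and k, all variables except items      high/low
survival_baseline      A only, items' baselines allowed         high/low
=====================  ======================================  ==========

ALSFRS-R item scores are excluded as features everywhere except the
baseline survival experiment (where the stair-climbing item is a known
prognostic baseline).  The ALSFRS-R total is excluded from the decline
experiments because the decline label is a deterministic function of
its fitted rate; admitting it would leak the label.

Learners: RUSBoost (implemented here: AdaBoost.M1 whose every boosting
round first randomly undersamples the majority class down to the
minority count — the standard remedy when fast progressors are the
rare class), AdaBoost, random forest, Gaussian naive Bayes and a single
decision tree, each behind a median-imputation pipeline fitted on the
training fold only.  Validation is a stratified 60/40 split repeated
100 times by default; classification is scored by ROC AUC and a
row-normalised confusion matrix at the 0.5 operating point, regression
by RMSE normalised to the observed label range (nRMSE, in %).
Variable importance is permutation importance on held-out folds, and
the reduced-model search returns the smallest top-N prefix of the
importance ranking that matches the full model's accuracy within a
declared tolerance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .synthetic import ALSFRS_ITEMS, ALSFRS_TOTAL

__all__ = [
    "Experiment",
    "FeatureTable",
    "LearnerSpec",
    "RUSBoostClassifier",
    "build_feature_table",
    "make_estimator",
    "train_learner",
    "repeated_holdout",
    "evaluate_classification",
    "evaluate_regression",
    "variable_importance",
    "reduced_model_search",
    "CVResult",
    "ReducedModelResult",
]

_MAX_SEED = 2**31 - 1


class Experiment(str, enum.Enum):
    DECLINE_TRAJECTORY = "decline_trajectory"
    DECLINE_BASELINE = "decline_baseline"
    K_BASELINE = "k_baseline"
    SURVIVAL_TRAJECTORY = "survival_trajectory"
    SURVIVAL_BASELINE = "survival_baseline"

    @property
    def uses_trajectories(self) -> bool:
        return self in (Experiment.DECLINE_TRAJECTORY, Experiment.SURVIVAL_TRAJECTORY)

    @property
    def mode(self) -> str:
        return "regress" if self is Experiment.K_BASELINE else "classify"


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features matrix with its label vector."""

    X: pd.DataFrame
    y: pd.Series
    experiment: Experiment


def build_feature_table(fits: pd.DataFrame, statics: pd.DataFrame | None,
                        labels: pd.Series, experiment) -> FeatureTable:
    """Assemble the feature matrix for one experiment.

    Parameters
    ----------
    fits : long DataFrame with subject_id, variable, A, k columns
        (exponential fits; k may be NaN for baseline-only series).
    statics : wide numeric DataFrame indexed by subject_id, or None.
    labels : Series indexed by subject_id (class labels or continuous k).
    experiment : Experiment or str.
    """
    experiment = Experiment(experiment)
    exclude = set(ALSFRS_ITEMS)
    if experiment is Experiment.SURVIVAL_BASELINE:
        exclude = set()
    if experiment in (Experiment.DECLINE_TRAJECTORY, Experiment.DECLINE_BASELINE,
                      Experiment.K_BASELINE):
        # the decline label/target derives from the total's fitted rate
        exclude_k_total = True
    else:
        exclude_k_total = False

    sub = fits[~fits["variable"].isin(exclude)]
    a_wide = sub.pivot(index="subject_id", columns="variable", values="A")
    a_wide.columns = [f"{v}__A" for v in a_wide.columns]
    parts = [a_wide]
    if experiment.uses_trajectories:
        k_wide = sub.pivot(index="subject_id", columns="variable", values="k")
        k_wide.columns = [f"{v}__k" for v in k_wide.columns]
        parts.append(k_wide)
    X = pd.concat(parts, axis=1)

    if experiment is Experiment.DECLINE_TRAJECTORY:
        X = X.drop(columns=[c for c in X.columns if c.startswith(ALSFRS_TOTAL + "__")])
    elif exclude_k_total:
        X = X.drop(columns=[ALSFRS_TOTAL + "__k"], errors="ignore")

    if statics is not None:
        X = X.join(statics, how="left")

    y = pd.Series(labels).dropna()
    common = X.index.intersection(y.index)
    X = X.loc[common].sort_index()
    y = y.loc[common].sort_index()
    X = X.dropna(axis=1, how="all")
    if X.shape[1] == 0:
        raise ValueError("no usable features for this experiment")
    return FeatureTable(X=X, y=y, experiment=experiment)


@dataclass(frozen=True)
class LearnerSpec:
    """Learning algorithm and hyperparameters for one experiment."""

    algorithm: str = "rusboost"
    mode: str = "classify"
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.5
    rf_trees: int = 500

    def __post_init__(self):
        allowed = {"rusboost", "adaboost", "random_forest", "naive_bayes",
                   "decision_tree"}
        if self.algorithm not in allowed:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.mode not in ("classify", "regress"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.algorithm == "rusboost" and self.mode != "classify":
            raise ValueError("rusboost supports classification only")
        if self.algorithm == "naive_bayes" and self.mode == "regress":
            raise ValueError("naive_bayes supports classification only")


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost.M1 with per-round random undersampling (RUSBoost).

    At every boosting round the majority class is randomly undersampled
    (without replacement, uniformly) to the minority-class count; the
    depth-limited base tree is trained on that balanced subsample with
    the current boosting weights, while the weighted error and the
    weight update are computed on the full training set.  The decision
    score is the alpha-weighted vote margin in [-1, 1].
    """

    def __init__(self, n_estimators=100, max_depth=3, learning_rate=0.5,
                 random_state=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("RUSBoost requires exactly two classes in training data")
        rng = np.random.default_rng(self.random_state)
        n = y_idx.size
        sign = 2.0 * y_idx - 1.0
        counts = np.bincount(y_idx, minlength=2)
        minority = int(np.argmin(counts))
        majority = 1 - minority
        n_min = int(counts[minority])

        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        self.round_class_counts_ = []
        for _ in range(self.n_estimators):
            maj_idx = np.flatnonzero(y_idx == majority)
            min_idx = np.flatnonzero(y_idx == minority)
            keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
            sel = np.concatenate([min_idx, keep_maj])
            sel_counts = np.bincount(y_idx[sel], minlength=2)
            assert sel_counts[0] == sel_counts[1], "round subsample must be balanced"
            self.round_class_counts_.append(tuple(int(c) for c in sel_counts))

            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(_MAX_SEED)),
            )
            sw = w[sel]
            tree.fit(X[sel], y_idx[sel], sample_weight=sw / sw.sum())

            pred = tree.predict(X)
            miss = pred != y_idx
            err = float(w[miss].sum() / w.sum())
            if err <= 0.0:
                self.estimators_.append(tree)
                self.alphas_.append(self.learning_rate * 10.0)
                break
            if err >= 0.5:
                continue  # uninformative round; weights untouched
            alpha = self.learning_rate * 0.5 * np.log((1.0 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            h = 2.0 * pred - 1.0
            w = w * np.exp(-alpha * sign * h)
            w /= w.sum()
        if not self.estimators_:  # all rounds uninformative: fall back
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(_MAX_SEED)),
            )
            tree.fit(X, y_idx, sample_weight=w)
            self.estimators_.append(tree)
            self.alphas_.append(1.0)
        self.alphas_ = np.asarray(self.alphas_, dtype=float)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree, alpha in zip(self.estimators_, self.alphas_):
            votes += alpha * (2.0 * tree.predict(X) - 1.0)
        return votes / self.alphas_.sum()

    def predict_proba(self, X):
        score = np.clip((self.decision_function(X) + 1.0) / 2.0, 0.0, 1.0)
        return np.column_stack([1.0 - score, score])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


def make_estimator(spec: LearnerSpec, seed=0) -> Pipeline:
    """Median-imputation + learner pipeline for one holdout repeat."""
    seed = int(seed) % _MAX_SEED
    if spec.mode == "classify":
        models = {
            "rusboost": lambda: RUSBoostClassifier(
                n_estimators=spec.n_estimators, max_depth=spec.max_depth,
                learning_rate=spec.learning_rate, random_state=seed,
            ),
            "adaboost": lambda: AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=spec.max_depth),
                n_estimators=spec.n_estimators, learning_rate=spec.learning_rate,
                random_state=seed,
            ),
            "random_forest": lambda: RandomForestClassifier(
                n_estimators=spec.rf_trees, random_state=seed, n_jobs=1,
            ),
            "naive_bayes": GaussianNB,
            "decision_tree": lambda: DecisionTreeClassifier(
                max_depth=spec.max_depth, random_state=seed,
            ),
        }
    else:
        models = {
            "adaboost": lambda: AdaBoostRegressor(
                estimator=DecisionTreeRegressor(max_depth=spec.max_depth),
                n_estimators=spec.n_estimators, learning_rate=spec.learning_rate,
                random_state=seed,
            ),
            "random_forest": lambda: RandomForestRegressor(
                n_estimators=spec.rf_trees, random_state=seed, n_jobs=1,
            ),
            "decision_tree": lambda: DecisionTreeRegressor(
                max_depth=spec.max_depth, random_state=seed,
            ),
        }
    return Pipeline(
        [("impute", SimpleImputer(strategy="median")), ("model", models[spec.algorithm]())]
    )


def train_learner(spec: LearnerSpec, X, y, seed=0):
    """Fit the spec's pipeline on (X, y) and return it."""
    if spec.mode == "classify" and pd.Series(y).nunique() < 2:
        raise ValueError("training fold contains a single class")
    est = make_estimator(spec, seed)
    est.fit(X, y)
    return est


def evaluate_classification(scores, labels, positive=None):
    """ROC AUC and row-normalised confusion matrix at score 0.5.

    ``labels`` may be any two values; ``positive`` names the class that
    high scores indicate (default: the lexicographically larger one).
    Returns ``(auc, confusion_pct)`` where confusion rows (actual
    class) sum to 100.
    """
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need both classes in labels")
    positive = positive if positive is not None else classes[-1]
    negative = [c for c in classes if c != positive][0]
    y = (labels == positive).to_numpy(int)
    scores = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, scores))
    pred = scores >= 0.5
    conf = pd.DataFrame(0.0, index=[negative, positive], columns=[negative, positive])
    for actual, name in ((0, negative), (1, positive)):
        mask = y == actual
        if mask.any():
            conf.loc[name, positive] = 100.0 * float(pred[mask].mean())
            conf.loc[name, negative] = 100.0 - conf.loc[name, positive]
    conf.index.name, conf.columns.name = "actual", "predicted"
    return auc, conf


def evaluate_regression(predictions, actuals) -> float:
    """RMSE normalised by the observed range of the actuals, in %."""
    actuals = np.asarray(actuals, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if actuals.size < 2:
        raise ValueError("need at least 2 actual values")
    rng = float(np.ptp(actuals))
    if rng == 0:
        raise ValueError("actuals have zero range; nRMSE undefined")
    rmse = float(np.sqrt(np.mean((predictions - actuals) ** 2)))
    return 100.0 * rmse / rng


@dataclass(frozen=True)
class CVResult:
    """Repeated-holdout performance of one learner on one experiment."""

    spec: LearnerSpec
    mode: str
    per_repeat: pd.DataFrame  # repeat, score (+auc for classify)
    mean_score: float
    sd_score: float
    confusion_pct: pd.DataFrame | None = None  # mean over repeats
    positive: object = None

    def summary(self) -> str:
        metric = "AUC" if self.mode == "classify" else "nRMSE (%)"
        lines = [
            f"{self.spec.algorithm} ({self.mode}), "
            f"{len(self.per_repeat)} x 60/40 holdout",
            f"  mean {metric} = {self.mean_score:.3f} (SD {self.sd_score:.3f})",
        ]
        if self.confusion_pct is not None:
            lines.append("  confusion (% of actual class):")
            lines.append(self.confusion_pct.round(1).to_string())
        return "\n".join(lines)


def _scores_from(est, X):
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def repeated_holdout(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec,
                     n_repeats=100, train_frac=0.6, seed=0,
                     positive=None) -> CVResult:
    """Stratified 60/40 holdout, repeated; scores on the held-out 40%.

    Classification reports mean/SD ROC AUC and the average confusion
    matrix at the 0.5 operating point; regression reports mean/SD
    nRMSE.  Imputation is fitted within each training fold.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows, confusions = [], []
    classify = spec.mode == "classify"
    if classify:
        classes = sorted(pd.Series(y).unique())
        positive = positive if positive is not None else classes[-1]
        if pd.Series(y).value_counts().min() < 2:
            raise ValueError("each class needs at least 2 subjects")
    for rep in range(n_repeats):
        child = int(rng.integers(_MAX_SEED))
        strat = y if classify else None
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=strat, random_state=child % (2**32 - 1)
        )
        est = train_learner(spec, X_tr, y_tr, seed=child)
        if classify:
            scores = _scores_from(est, X_te)
            # orient scores to the positive class
            model_classes = list(est.named_steps["model"].classes_)
            if model_classes[-1] != positive:
                scores = 1.0 - scores
            auc, conf = evaluate_classification(scores, y_te, positive=positive)
            rows.append({"repeat": rep, "score": auc})
            confusions.append(conf)
        else:
            nrmse = evaluate_regression(est.predict(X_te), y_te)
            rows.append({"repeat": rep, "score": nrmse})
    per_repeat = pd.DataFrame(rows)
    conf_mean = None
    if confusions:
        conf_mean = sum(confusions) / len(confusions)
    return CVResult(
        spec=spec,
        mode=spec.mode,
        per_repeat=per_repeat,
        mean_score=float(per_repeat["score"].mean()),
        sd_score=float(per_repeat["score"].std(ddof=1)) if n_repeats > 1 else 0.0,
        confusion_pct=conf_mean,
        positive=positive,
    )


def variable_importance(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec,
                        n_repeats=10, train_frac=0.6, seed=0,
                        n_permutations=3) -> pd.Series:
    """Held-out permutation importance averaged over holdout repeats.

    Returns a Series of importance scores sorted descending, with ties
    broken by feature name for determinism.
    """
    rng = np.random.default_rng(seed)
    total = pd.Series(0.0, index=X.columns)
    classify = spec.mode == "classify"
    for _ in range(n_repeats):
        child = int(rng.integers(_MAX_SEED))
        strat = y if classify else None
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=strat, random_state=child % (2**32 - 1)
        )
        est = train_learner(spec, X_tr, y_tr, seed=child)
        scoring = "roc_auc" if classify else "neg_root_mean_squared_error"
        imp = permutation_importance(
            est, X_te, y_te, scoring=scoring, n_repeats=n_permutations,
            random_state=child % (2**32 - 1),
        )
        total += pd.Series(imp.importances_mean, index=X.columns)
    mean = total / n_repeats
    order = sorted(mean.index, key=lambda name: (-mean[name], name))
    return mean.loc[order]


@dataclass(frozen=True)
class ReducedModelResult:
    """Smallest importance-ranked feature prefix matching full accuracy."""

    features: tuple
    result: CVResult
    full_result: CVResult
    flagged: bool  # True when no prefix met the tolerance (full set kept)


def reduced_model_search(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec,
                         ranking, tol=None, n_repeats=20, seed=0,
                         full_result: CVResult | None = None,
                         positive=None) -> ReducedModelResult:
    """Scan N = 1, 2, ... top-ranked features until accuracy is recovered.

    A prefix qualifies when its mean AUC is within ``tol`` (default
    0.01) of the full model's, or its mean nRMSE within ``tol``
    percentage points (default 1.0) above the full model's.
    """
    ranking = [f for f in ranking if f in X.columns]
    if not ranking:
        raise ValueError("ranking is empty")
    classify = spec.mode == "classify"
    if tol is None:
        tol = 0.01 if classify else 1.0
    if full_result is None:
        full_result = repeated_holdout(
            X, y, spec, n_repeats=n_repeats, seed=seed, positive=positive
        )
    for n_top in range(1, len(ranking) + 1):
        feats = ranking[:n_top]
        res = repeated_holdout(
            X[feats], y, spec, n_repeats=n_repeats, seed=seed, positive=positive
        )
        ok = (
            res.mean_score >= full_result.mean_score - tol
            if classify
            else res.mean_score <= full_result.mean_score + tol
        )
        if ok:
            return ReducedModelResult(tuple(feats), res, full_result, flagged=False)
    return ReducedModelResult(tuple(ranking), full_result, full_result, flagged=True)
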