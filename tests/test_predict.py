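"""Learners, repeated-holdout validation, importance and reduction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from alscourse.predict import (
    Experiment,
    LearnerSpec,
    RUSBoostClassifier,
    build_feature_table,
    evaluate_classification,
    evaluate_regression,
    reduced_model_search,
    repeated_holdout,
    train_learner,
    variable_importance,
)


def _imbalanced_toy(n_major=900, n_minor=100, n_noise=3, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    n = n_major + n_minor
    y = np.array(["slow"] * n_major + ["fast"] * n_minor)
    signal = np.where(y == "fast", 2.0, -2.0) + rng.normal(0, 0.3 if separable else 100.0, n)
    X = pd.DataFrame({"signal": signal})
    for j in range(n_noise):
        X[f"noise{j}"] = rng.normal(size=n)
    return X, pd.Series(y)


# -------------------------------------------------------------- RUSBoost


def test_rusboost_balances_every_round():
    X, y = _imbalanced_toy()
    clf = RUSBoostClassifier(n_estimators=20, random_state=0)
    clf.fit(X.values, y.values)
    assert len(clf.round_class_counts_) >= 1
    for c0, c1 in clf.round_class_counts_:
        assert c0 == c1 == 100  # undersampled to the minority count


def test_rusboost_separable_data_perfect_training_auc():
    X, y = _imbalanced_toy()
    clf = RUSBoostClassifier(n_estimators=20, random_state=0)
    clf.fit(X.values, y.values)
    auc, _ = evaluate_classification(
        clf.predict_proba(X.values)[:, 1], y, positive=sorted(set(y))[-1]
    )
    # orientation: proba column 1 follows classes_[-1]
    assert auc == pytest.approx(1.0)


def test_rusboost_requires_two_classes():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        RUSBoostClassifier().fit(X.values, np.array(["a", "a", "a"]))


def test_rusboost_deterministic():
    X, y = _imbalanced_toy(seed=3, separable=False)
    p1 = RUSBoostClassifier(n_estimators=10, random_state=5).fit(X.values, y.values)
    p2 = RUSBoostClassifier(n_estimators=10, random_state=5).fit(X.values, y.values)
    assert np.array_equal(p1.decision_function(X.values), p2.decision_function(X.values))


def test_single_round_adaboost_equals_a_lone_stump():
    X, y = _imbalanced_toy(n_major=60, n_minor=60, seed=2)
    spec = LearnerSpec("adaboost", "classify", n_estimators=1, max_depth=1,
                       learning_rate=1.0)
    boosted = train_learner(spec, X, y, seed=0)
    stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    assert np.array_equal(boosted.predict(X), stump.predict(X))


# ------------------------------------------------------------- metrics


def test_auc_perfect_separation():
    auc, _ = evaluate_classification(
        [0.9, 0.8, 0.1, 0.2], ["pos", "pos", "neg", "neg"], positive="pos"
    )
    assert auc == 1.0


def test_auc_hand_rank_half():
    auc, _ = evaluate_classification(
        [0.6, 0.4, 0.5, 0.5], ["pos", "pos", "neg", "neg"], positive="pos"
    )
    assert auc == pytest.approx(0.5)


def test_confusion_rows_are_percentages():
    scores = [0.9, 0.9, 0.9, 0.9]  # everything called positive
    _, conf = evaluate_classification(
        scores, ["pos", "pos", "neg", "neg"], positive="pos"
    )
    assert conf.loc["pos", "pos"] == 100.0
    assert conf.loc["neg", "neg"] == 0.0
    assert conf.sum(axis=1).tolist() == [100.0, 100.0]


def test_nrmse_perfect_and_shift_identities():
    assert evaluate_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    # constant shift c over range R gives 100*c/R %
    assert evaluate_regression([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(50.0)


def test_nrmse_hand_value():
    assert evaluate_regression([0, 1, 2, 5], [0, 1, 2, 3]) == pytest.approx(
        100.0 / 3.0
    )


def test_nrmse_zero_range_errors():
    with pytest.raises(ValueError):
        evaluate_regression([1.0, 2.0], [3.0, 3.0])


# -------------------------------------------------------- feature table


def _toy_fits():
    rows = []
    for s in ("s1", "s2", "s3", "s4"):
        for var in ("weight", "pulse", "albumin", "alsfrs_r_total", "alsfrs_r_q9"):
            rows.append((s, var, 40.0, 0.001))
    fits = pd.DataFrame(rows, columns=["subject_id", "variable", "A", "k"])
    # one missing decline rate: row must survive as a missing cell
    fits.loc[(fits.subject_id == "s1") & (fits.variable == "weight"), "k"] = np.nan
    return fits


def test_feature_table_arity_and_exclusions():
    fits = _toy_fits()
    labels = pd.Series({"s1": "fast", "s2": "slow", "s3": "slow", "s4": "fast"})
    traj = build_feature_table(fits, None, labels, Experiment.DECLINE_TRAJECTORY)
    # items and the label-source total excluded; A and k per variable
    assert sorted(traj.X.columns) == [
        "albumin__A", "albumin__k", "pulse__A", "pulse__k",
        "weight__A", "weight__k",
    ]
    assert "s1" in traj.X.index
    assert np.isnan(traj.X.loc["s1", "weight__k"])

    base = build_feature_table(fits, None, labels, Experiment.DECLINE_BASELINE)
    assert not any(c.endswith("__k") for c in base.X.columns)
    assert "alsfrs_r_total__A" in base.X.columns  # baseline total is fair game

    surv = build_feature_table(fits, None, labels, Experiment.SURVIVAL_BASELINE)
    assert "alsfrs_r_q9__A" in surv.X.columns  # items allowed here only
    traj_surv = build_feature_table(fits, None, labels, Experiment.SURVIVAL_TRAJECTORY)
    assert "alsfrs_r_q9__A" not in traj_surv.X.columns
    assert "alsfrs_r_total__k" in traj_surv.X.columns


def test_feature_table_joins_statics():
    fits = _toy_fits()
    labels = pd.Series({"s1": "fast", "s2": "slow", "s3": "slow", "s4": "fast"})
    statics = pd.DataFrame({"age": [50.0, 60, 70, 55]},
                           index=["s1", "s2", "s3", "s4"])
    statics.index.name = "subject_id"
    table = build_feature_table(fits, statics, labels, Experiment.DECLINE_BASELINE)
    assert "age" in table.X.columns


# ------------------------------------------------------ repeated holdout


def test_holdout_deterministic_given_seed():
    X, y = _imbalanced_toy(n_major=80, n_minor=40, seed=4)
    spec = LearnerSpec("decision_tree", "classify")
    r1 = repeated_holdout(X, y, spec, n_repeats=5, seed=9, positive="fast")
    r2 = repeated_holdout(X, y, spec, n_repeats=5, seed=9, positive="fast")
    pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)
    assert r1.mean_score == r2.mean_score


def test_null_labels_give_chance_auc():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(200, 10)))
    X.columns = [f"f{i}" for i in X.columns]
    y = pd.Series(np.where(rng.random(200) < 0.5, "a", "b"))
    res = repeated_holdout(X, y, LearnerSpec("rusboost", "classify"),
                           n_repeats=10, seed=1, positive="b")
    assert 0.4 <= res.mean_score <= 0.6


def test_planted_signal_gives_high_auc():
    X, y = _imbalanced_toy(n_major=150, n_minor=60, seed=5)
    res = repeated_holdout(X, y, LearnerSpec("rusboost", "classify"),
                           n_repeats=10, seed=1, positive="fast")
    assert res.mean_score > 0.95
    assert res.confusion_pct.loc["fast", "fast"] > 80.0


def test_holdout_regression_mode():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"x": rng.normal(size=150)})
    y = pd.Series(3.0 * X["x"] + rng.normal(0, 0.1, 150))
    res = repeated_holdout(
        X, y, LearnerSpec("random_forest", "regress", rf_trees=50),
        n_repeats=5, seed=2,
    )
    assert res.mode == "regress"
    assert res.mean_score < 15.0  # nRMSE %


# ----------------------------------------------- importance & reduction


def test_importance_ranks_planted_feature_first():
    X, y = _imbalanced_toy(n_major=120, n_minor=80, seed=7)
    imp = variable_importance(
        X, y, LearnerSpec("decision_tree", "classify"), n_repeats=4, seed=0
    )
    assert imp.index[0] == "signal"
    assert imp.iloc[0] > 0.2
    assert imp.drop("signal").abs().max() < 0.1  # noise stays near zero


def test_reduced_search_finds_small_sufficient_set():
    rng = np.random.default_rng(8)
    n = 240
    y = pd.Series(np.where(rng.random(n) < 0.4, "fast", "slow"))
    X = pd.DataFrame(rng.normal(size=(n, 20)),
                     columns=[f"noise{i}" for i in range(20)])
    planted = []
    for j in range(4):
        name = f"planted{j}"
        planted.append(name)
        # individually weak, jointly strong: several are needed to
        # recover the full model's accuracy
        X[name] = np.where(y == "fast", 1.0, -1.0) + rng.normal(0, 1.6, n)
    spec = LearnerSpec("rusboost", "classify", n_estimators=30)
    imp = variable_importance(X, y, spec, n_repeats=3, seed=1)
    res = reduced_model_search(X, y, spec, imp.index, n_repeats=5, seed=1,
                               positive="fast")
    assert not res.flagged
    assert len(res.features) <= 6
    assert sum(f in planted for f in res.features) >= 3


def test_reduced_search_degenerate_tolerance_returns_one():
    X, y = _imbalanced_toy(n_major=80, n_minor=60, seed=9)
    spec = LearnerSpec("decision_tree", "classify")
    res = reduced_model_search(X, y, spec, ["signal", "noise0"], tol=1.0,
                               n_repeats=3, seed=0, positive="fast")
    assert res.features == ("signal",)


def test_reduced_search_flags_when_nothing_suffices():
    # ranking restricted to noise columns can never match a full model
    # that also sees the signal: the full set comes back flagged
    X, y = _imbalanced_toy(n_major=80, n_minor=60, seed=10)
    spec = LearnerSpec("decision_tree", "classify")
    res = reduced_model_search(X, y, spec, ["noise0", "noise1"], n_repeats=3,
                               seed=0, positive="fast")
    assert res.flagged
    assert res.result is res.full_result


def test_learner_spec_validation():
    with pytest.raises(ValueError):
        LearnerSpec("rusboost", "regress")
    with pytest.raises(ValueError):
        LearnerSpec("unknown", "classify")
    with pytest.raises(ValueError):
        LearnerSpec("naive_bayes", "regress")
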