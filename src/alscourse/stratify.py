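"""Unsupervised stratification into decline and death-risk classes.

Two binary patient classes are derived without supervision:

* **fast / slow progressors** — k-means and PAM (partitioning around
  medoids) clustering of the fitted per-day ALSFRS-R decline rate
  ``k``; the method whose clusters are further apart (larger gap in
  median ``|k|``) is retained, and the cluster with the larger median
  ``|k|`` is labelled *fast*.
* **high / low death risk** — binary k-means on days from trial start
  to death, with the last follow-up day standing in for subjects whose
  death was never recorded (a proxy that understates survival).  The
  class boundary is reported as the midpoint between the two cluster
  centres; the cluster with the smaller centre is *high* risk.

Cluster counts are validated by average silhouette width; on this kind
of cohort a binary split is optimal for both quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "pam",
    "optimal_cluster_count",
    "DeclineClassAssignment",
    "derive_decline_classes",
    "derive_survival_outcomes",
    "SurvivalClassResult",
    "derive_survival_classes",
    "cross_tabulate",
]


def pam(values, n_clusters, max_iter=100):
    """Partitioning around medoids (BUILD + SWAP) on 1-D data.

    Greedy BUILD initialisation followed by exhaustive SWAP steps until
    no single medoid/non-medoid exchange lowers the total absolute
    deviation.  Deterministic.  Returns ``(labels, medoids)`` with
    medoid values sorted ascending.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n_clusters >= n:
        raise ValueError("need more points than clusters")
    dist = np.abs(x[:, None] - x[None, :])

    # BUILD: first medoid minimises total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < n_clusters:
        cur = dist[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for i, m in enumerate(medoids):
            others = [j for j in range(n) if j not in medoids]
            trial = list(medoids)
            for h in others:
                trial[i] = h
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids = c, list(trial)
                    improved = True
            if improved:
                break
        if not improved:
            break

    medoid_vals = np.sort(x[medoids])
    centers_idx = np.array(sorted(medoids, key=lambda j: x[j]))
    labels = np.argmin(dist[:, centers_idx], axis=1)
    return labels, medoid_vals


def _kmeans(values, n_clusters, seed):
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=n_clusters, n_init=25, random_state=seed)
    labels = km.fit_predict(x)
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    remap = np.empty_like(order)
    remap[order] = np.arange(n_clusters)
    return remap[labels], centers[order]


def optimal_cluster_count(values, kmax=5, seed=0):
    """Cluster count maximising average silhouette width (k-means).

    Scans k = 2..kmax; deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError("values are degenerate (all equal)")
    scores = {}
    for k in range(2, min(kmax, n_distinct) + 1):
        labels, _ = _kmeans(x, k, seed)
        scores[k] = silhouette_score(x, labels)
    return max(scores, key=lambda k: (scores[k], -k))


@dataclass(frozen=True)
class DeclineClassAssignment:
    """Binary fast/slow progressor labels from the fitted decline rate."""

    labels: pd.Series  # subject_id -> "fast"/"slow", selected method
    method: str  # "kmeans" or "pam"
    centers: np.ndarray  # selected method's centres/medoids, ascending k
    n_clusters: int
    kmeans_labels: pd.Series
    pam_labels: pd.Series
    median_gap: dict  # method -> |median |k| fast - median |k| slow|

    @property
    def fast_fraction(self) -> float:
        return float((self.labels == "fast").mean())


def _binary_fast_slow(k_values: pd.Series, labels: np.ndarray):
    """Label the cluster with the larger median |k| as fast."""
    med = [np.median(np.abs(k_values[labels == c])) for c in (0, 1)]
    fast_cluster = int(np.argmax(med))
    names = np.where(labels == fast_cluster, "fast", "slow")
    gap = abs(med[1] - med[0])
    return pd.Series(names, index=k_values.index, name="decline_class"), gap


def derive_decline_classes(k_values: pd.Series, seed=0) -> DeclineClassAssignment:
    """Cluster fitted ALSFRS-R decline rates into fast/slow classes.

    Runs both k-means and PAM at two clusters and keeps the method with
    the larger between-cluster gap in median ``|k|``.
    """
    k_values = pd.Series(k_values).astype(float)
    if len(k_values) < 4:
        raise ValueError("need at least 4 subjects to stratify")
    if np.ptp(k_values.values) == 0:
        raise ValueError("decline rates are degenerate (all equal)")

    km_raw, km_centers = _kmeans(k_values.values, 2, seed)
    pam_raw, pam_medoids = pam(k_values.values, 2)
    km_labels, km_gap = _binary_fast_slow(k_values, km_raw)
    pam_labels, pam_gap = _binary_fast_slow(k_values, pam_raw)

    method = "kmeans" if km_gap >= pam_gap else "pam"
    labels = km_labels if method == "kmeans" else pam_labels
    centers = km_centers if method == "kmeans" else pam_medoids
    return DeclineClassAssignment(
        labels=labels,
        method=method,
        centers=np.asarray(centers, dtype=float),
        n_clusters=2,
        kmeans_labels=km_labels,
        pam_labels=pam_labels,
        median_gap={"kmeans": float(km_gap), "pam": float(pam_gap)},
    )


def derive_survival_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Days-to-event with the last follow-up day as a death-day proxy.

    Input columns: ``subject_id``, ``death_day`` (NaN when unrecorded),
    ``last_followup_day``.  Output adds ``days`` (death day when
    recorded, else last follow-up) and ``event_observed``; subjects with
    neither day are dropped.
    """
    out = outcomes.copy()
    has_death = out["death_day"].notna()
    has_fup = out["last_followup_day"].notna()
    out = out[has_death | has_fup].copy()
    out["event_observed"] = out["death_day"].notna()
    out["days"] = out["death_day"].where(out["event_observed"], out["last_followup_day"])
    out["days"] = out["days"].astype(float)
    if (out["days"] < 0).any():
        raise ValueError("negative days-to-event")
    return out


@dataclass(frozen=True)
class SurvivalClassResult:
    """Binary high/low death-risk labels with the separating threshold."""

    outcomes: pd.DataFrame  # with risk_class column
    threshold_days: float  # midpoint between cluster centres
    centers: np.ndarray  # ascending (high-risk centre first)

    @property
    def high_risk_fraction(self) -> float:
        return float((self.outcomes["risk_class"] == "high").mean())


def derive_survival_classes(outcomes: pd.DataFrame, seed=0) -> SurvivalClassResult:
    """Binary k-means on days-to-event; smaller-centre cluster = high risk."""
    out = outcomes.copy()
    if len(out) < 4:
        raise ValueError("need at least 4 outcomes to stratify")
    days = out["days"].to_numpy(dtype=float)
    if np.ptp(days) == 0:
        raise ValueError("days-to-event are degenerate (all equal)")
    labels, centers = _kmeans(days, 2, seed)
    out["risk_class"] = np.where(labels == 0, "high", "low")
    threshold = float(centers.mean())
    return SurvivalClassResult(outcomes=out, threshold_days=threshold,
                               centers=np.asarray(centers, dtype=float))


def cross_tabulate(decline: pd.Series, risk: pd.Series):
    """2x2 counts and percentages over subjects holding both labels.

    Returns ``(counts, percentages)`` DataFrames with decline class on
    the rows and risk class on the columns; percentages are of the
    intersection total.
    """
    common = decline.index.intersection(risk.index)
    if common.empty:
        raise ValueError("no subjects with both classifications")
    counts = pd.crosstab(decline.loc[common], risk.loc[common])
    counts = counts.reindex(index=["fast", "slow"], columns=["high", "low"],
                            fill_value=0)
    pct = 100.0 * counts / counts.values.sum()
    return counts, pct
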