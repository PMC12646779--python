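"""k-means classification of animals into three movement strategies.

Animals are clustered on metrics 1--3 (seasonal, summer and winter overlap;
all on the shared [0, 1] scale, so no standardization is applied) with k = 3.
Clusters are named by their centroids:

* highest seasonal-overlap centroid -> ``resident`` (high overlap year-round);
* of the remaining two, highest winter-overlap centroid ->
  ``dual_range_migrant`` (distinct but repeated seasonal ranges);
* the other -> ``multi_range_migrant`` (switches winter ranges across years).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

METRIC_COLUMNS = ("seasonal_overlap", "summer_overlap", "winter_overlap")

STRATEGY_LABELS = ("resident", "dual_range_migrant", "multi_range_migrant")


def label_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Map cluster indices to strategy names from their (m1, m2, m3) centroids."""
    centroids = np.asarray(centroids, float)
    if centroids.shape != (3, 3):
        raise ValueError("expected three centroids of the three metrics")
    m1 = centroids[:, 0]
    order = np.argsort(-m1, kind="stable")
    if abs(m1[order[0]] - m1[order[1]]) <= np.finfo(float).eps * max(1.0, abs(m1[order[0]])):
        raise ValueError("seasonal-overlap centroids tie at machine precision; "
                         "label clusters manually")
    resident = int(order[0])
    rest = [i for i in range(3) if i != resident]
    dual = int(rest[np.argmax(centroids[rest, 2])])
    multi = next(i for i in rest if i != dual)
    return {resident: "resident", dual: "dual_range_migrant",
            multi: "multi_range_migrant"}


class StrategyClassifier(ClusterMixin, BaseEstimator):
    """Lloyd's k-means (k-means++ starts) plus the centroid-labelling rule.

    Parameters
    ----------
    n_clusters : int, default 3
        Number of strategies; the study design is three.
    n_init : int, default 50
        Random restarts; the best within-cluster sum of squares is kept.
    random_state : int, default 0
        Seed; results are deterministic for a fixed value.

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, 3) centroids in metric space.
    labels_ : cluster index per animal.
    strategies_ : strategy name per animal.
    cluster_to_strategy_ : mapping cluster index -> strategy name.
    inertia_ : within-cluster sum of squares of the kept solution.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 50,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_animals, 3): metrics 1-3")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} complete animals, "
                f"got {X.shape[0]}")
        if np.nanmin(X) < -1e-9 or np.nanmax(X) > 1 + 1e-9:
            raise ValueError("metrics must lie in [0, 1]")
        km = KMeans(n_clusters=self.n_clusters, init="k-means++",
                    n_init=self.n_init, random_state=self.random_state)
        km.fit(X)
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        self._kmeans_ = km
        if self.n_clusters == 3:
            self.cluster_to_strategy_ = label_clusters(self.cluster_centers_)
            self.strategies_ = np.array(
                [self.cluster_to_strategy_[int(c)] for c in self.labels_])
        return self

    def predict(self, X) -> np.ndarray:
        """Strategy name for each row of new metrics."""
        check_is_fitted(self, "_kmeans_")
        labels = self._kmeans_.predict(np.asarray(X, float))
        return np.array([self.cluster_to_strategy_[int(c)] for c in labels])


def kmeans_strategies(metrics: pd.DataFrame, k: int = 3, n_init: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """Cluster a metrics table; returns the strategy-assignment table.

    ``metrics`` must carry ``animal_id`` and the three metric columns; the
    result has animal_id, strategy, cluster_index, the metrics and the
    cluster centroid coordinates.
    """
    missing = [c for c in ("animal_id", *METRIC_COLUMNS)
               if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    X = metrics[list(METRIC_COLUMNS)].to_numpy(float)
    clf = StrategyClassifier(n_clusters=k, n_init=n_init, random_state=seed)
    clf.fit(X)
    out = metrics[["animal_id", *METRIC_COLUMNS]].copy()
    out["cluster_index"] = clf.labels_
    out["strategy"] = clf.strategies_
    cent = clf.cluster_centers_[clf.labels_]
    out["centroid_seasonal"] = cent[:, 0]
    out["centroid_summer"] = cent[:, 1]
    out["centroid_winter"] = cent[:, 2]
    return out
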