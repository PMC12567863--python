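"""Three-step cluster refinement: feature screen, PCA, silhouette-picked k.

Lifestyle clustering of per-user daytime aggregates proceeds as:

1. **Feature removal** — of every highly correlated pair (|r| >= 0.90) the
   member with the lower ANOVA F-statistic against provisional labels is
   dropped; features in the bottom decile of F are dropped as well.
   Provisional labels come from a k=3 K-means on all standardized features.
2. **PCA** — the smallest number of components whose cumulative explained
   variance reaches the target (default 85%).
3. **K-means** — k-means++ with 50 restarts, max_iter 500, tol 1e-4,
   fixed random_state 42; k is chosen over 2..6 by the highest silhouette
   score in the PCA space, ties going to the smaller k.

Users whose own silhouette falls below ``ambiguity_threshold`` are flagged
as ambiguous: they keep a label for recommendation fallback but are
excluded from cluster profiling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.metrics import silhouette_samples, silhouette_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "select_features",
    "fit_pca",
    "fit_kmeans",
    "silhouette",
    "select_k",
    "ClusterRefiner",
    "user_cluster_table",
]

KMEANS_CONFIG = dict(init="k-means++", n_init=50, max_iter=500, tol=1e-4)
DEFAULT_RANDOM_STATE = 42
K_RANGE = range(2, 7)


def _provisional_labels(X: np.ndarray, random_state: int) -> np.ndarray:
    """k=3 K-means on all standardized features, used only for the F screen."""
    k = min(3, X.shape[0])
    return KMeans(n_clusters=k, random_state=random_state, **KMEANS_CONFIG).fit_predict(X)


def select_features(
    table: pd.DataFrame,
    corr_threshold: float = 0.90,
    f_quantile: float = 0.10,
    p_threshold: float = 0.05,
    random_state: int = DEFAULT_RANDOM_STATE,
) -> list[str]:
    """Names surviving the correlation + ANOVA-F screen.

    Three rules, all judged against provisional labels (a k=3 K-means on
    every standardized feature):

    * of each pair with |r| >= ``corr_threshold``, the lower-F member drops;
    * features whose ANOVA F is not significant at ``p_threshold`` drop —
      these carry no cluster signal at all, only variance;
    * features in the bottom ``f_quantile`` of the surviving F scores drop
      (skipped if it would leave fewer than two features).

    Deterministic given ``random_state`` (which seeds the provisional
    K-means).  Raises if the screen would drop everything.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 samples")
    X = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    labels = _provisional_labels(X, random_state)
    f_scores, p_values = f_classif(X, labels)
    fs = pd.Series(np.nan_to_num(f_scores, nan=0.0), index=table.columns)
    ps = pd.Series(np.nan_to_num(p_values, nan=1.0), index=table.columns)

    corr = np.corrcoef(X, rowvar=False)
    dropped: set[str] = set()
    cols = list(table.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) >= corr_threshold:
                a, b = cols[i], cols[j]
                if a in dropped or b in dropped:
                    continue
                dropped.add(a if fs[a] < fs[b] else b)

    survivors = [c for c in cols if c not in dropped and ps[c] <= p_threshold]
    if not survivors:  # degenerate: nothing significant; fall back to F order
        survivors = [c for c in cols if c not in dropped]
    cutoff = fs[survivors].quantile(f_quantile)
    trimmed = [c for c in survivors if fs[c] >= cutoff]
    if len(trimmed) >= 2:
        survivors = trimmed
    if not survivors:
        raise ValueError("feature screen removed every feature")
    return survivors


def fit_pca(table: pd.DataFrame | np.ndarray, variance_target: float = 0.85) -> PCA:
    """PCA keeping the smallest m with cumulative explained variance >= target."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    X = np.asarray(table, dtype=float)
    full = PCA().fit(X)
    cum = np.cumsum(full.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return PCA(n_components=m).fit(X)


def fit_kmeans(scores: np.ndarray, k: int,
               random_state: int = DEFAULT_RANDOM_STATE) -> KMeans:
    """K-means with the fixed configuration (k-means++/50/500/1e-4)."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds n={scores.shape[0]} samples")
    return KMeans(n_clusters=k, random_state=random_state, **KMEANS_CONFIG).fit(scores)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) under Euclidean distance."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    return float(silhouette_score(np.asarray(points, dtype=float), labels))


def select_k(
    scores: np.ndarray,
    k_range=K_RANGE,
    random_state: int = DEFAULT_RANDOM_STATE,
) -> tuple[int, KMeans, dict[int, float]]:
    """Fit K-means per k and keep the silhouette argmax (ties -> smaller k)."""
    by_k: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in k_range:
        km = fit_kmeans(scores, k, random_state)
        models[k] = km
        by_k[k] = silhouette(scores, km.labels_)
    best = max(sorted(by_k), key=lambda k: (by_k[k], -k))
    return best, models[best], by_k


class ClusterRefiner(BaseEstimator, ClusterMixin):
    """Feature screen -> PCA -> silhouette-selected K-means, as an estimator.

    Parameters
    ----------
    corr_threshold : |r| at or above which a feature pair is redundant.
    f_quantile : fraction of lowest-F features dropped outright.
    variance_target : cumulative explained-variance ratio the PCA must reach.
    k_range : candidate cluster counts.
    ambiguity_threshold : per-sample silhouette below which a user is
        flagged ambiguous (excluded from cluster profiling).
    random_state : seeds every stochastic stage.

    Attributes (after ``fit``)
    --------------------------
    retained_features_, scaler_, pca_, k_, kmeans_, labels_,
    silhouette_by_k_, silhouette_, sample_silhouette_, ambiguous_
    """

    def __init__(self, corr_threshold: float = 0.90, f_quantile: float = 0.10,
                 p_threshold: float = 0.05,
                 variance_target: float = 0.85, k_range=tuple(K_RANGE),
                 ambiguity_threshold: float = 0.1,
                 random_state: int = DEFAULT_RANDOM_STATE):
        self.corr_threshold = corr_threshold
        self.f_quantile = f_quantile
        self.p_threshold = p_threshold
        self.variance_target = variance_target
        self.k_range = k_range
        self.ambiguity_threshold = ambiguity_threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ClusterRefiner":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        self.retained_features_ = select_features(
            X, self.corr_threshold, self.f_quantile, self.p_threshold,
            self.random_state,
        )
        kept = X[self.retained_features_]
        self.scaler_ = StandardScaler().fit(kept.to_numpy(dtype=float))
        Z = self.scaler_.transform(kept.to_numpy(dtype=float))
        self.pca_ = fit_pca(Z, self.variance_target)
        scores = self.pca_.transform(Z)
        self.k_, self.kmeans_, self.silhouette_by_k_ = select_k(
            scores, self.k_range, self.random_state
        )
        self.labels_ = self.kmeans_.labels_
        self.silhouette_ = self.silhouette_by_k_[self.k_]
        self.sample_silhouette_ = silhouette_samples(scores, self.labels_)
        self.ambiguous_ = self.sample_silhouette_ < self.ambiguity_threshold
        self.index_ = X.index
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Project new samples into the fitted PCA space."""
        kept = pd.DataFrame(X)[self.retained_features_].to_numpy(dtype=float)
        return self.pca_.transform(self.scaler_.transform(kept))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.kmeans_.predict(self.transform(X))

    def labels_series(self) -> pd.Series:
        """Labels on the fitted index, ambiguous users set to -1."""
        lab = pd.Series(self.labels_, index=self.index_, name="cluster")
        lab[self.ambiguous_] = -1
        return lab

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.get_params(),
            "retained_features": self.retained_features_,
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "pca_components": self.pca_.components_.tolist(),
            "pca_mean": self.pca_.mean_.tolist(),
            "explained_variance_ratio": self.pca_.explained_variance_ratio_.tolist(),
            "k": int(self.k_),
            "centroids": self.kmeans_.cluster_centers_.tolist(),
            "labels": np.asarray(self.labels_).tolist(),
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k_.items()},
        }
        payload["params"]["k_range"] = list(payload["params"]["k_range"])
        Path(path).write_text(json.dumps(payload, indent=1))


def user_cluster_table(nights: pd.DataFrame) -> pd.DataFrame:
    """Per-user daytime/physiology aggregates used as clustering input.

    Sleep outcomes are deliberately excluded — they are what the clusters
    are later profiled against, not inputs.
    """
    g = nights.groupby("user_id")
    table = pd.DataFrame({
        "steps_mean": g["steps"].mean(),
        "steps_cv": g["steps"].std(ddof=1) / g["steps"].mean(),
        "hr_mean": g["hr_mean"].mean(),
        "hr_sd_mean": g["hr_sd"].mean(),
        "stress_mean": g["stress"].mean(),
        "fatigue_mean": g["fatigue"].mean(),
        "light_mean": g["light"].mean(),
        "noise_mean": g["noise"].mean(),
        "temperature_mean": g["temperature"].mean(),
        "humidity_mean": g["humidity"].mean(),
    })
    return table.dropna(axis=0)
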