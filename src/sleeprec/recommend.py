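"""Cluster-restricted similar-user matching and feedback-based re-ranking.

Two collaborative stages sit on top of the profiles and clusters:

* **CBSUR** (cluster-based similar-user recommendation): within the target
  user's cluster, among users with a *higher* aggregated sleep-quality
  score, pick the one with the highest cosine similarity of profile
  feature vectors; that user's habits become the reference.

* **PFRA** (personalized feedback-based re-ranking): predict the target's
  rating of an unrated item as the similarity-weighted mean of the ratings
  its top-K most similar neighbours gave it,
  ``R_hat(u, i) = sum_v sim(u, v) R(v, i) / sum_v sim(u, v)``,
  then return the top-K items by predicted rating.  Neighbourhoods are
  restricted to the user's cluster (falling back to the global pool when
  the cluster is too small) and negative similarities are excluded so the
  prediction stays a convex combination of observed neighbour ratings.

Items live in a small catalog of parameterized guidance templates in two
categories: sleep-schedule adjustment and lifestyle/activity optimization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CatalogItem",
    "ItemCatalog",
    "default_catalog",
    "cosine_sim",
    "cbsur",
    "PFRARecommender",
    "render_recommendation",
]


@dataclass(frozen=True)
class CatalogItem:
    item_id: str
    category: str  # sleep_schedule_adjustment | lifestyle_activity_optimization
    template: str
    params: dict = field(default_factory=dict)
    attributes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # attribute space: (schedule-regularity, activity, stress/environment relief)


@dataclass
class ItemCatalog:
    items: list[CatalogItem]

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in catalog")
        bad = {it.category for it in self.items} - {
            "sleep_schedule_adjustment", "lifestyle_activity_optimization"}
        if bad:
            raise ValueError(f"unknown item categories: {bad}")

    def __len__(self):
        return len(self.items)

    def __getitem__(self, item_id: str) -> CatalogItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def attribute_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [it.attributes for it in self.items], index=self.ids,
            columns=["schedule", "activity", "relief"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [dataclasses_asdict(it) for it in self.items], indent=1))


def dataclasses_asdict(item: CatalogItem) -> dict:
    return {"item_id": item.item_id, "category": item.category,
            "template": item.template, "params": item.params,
            "attributes": list(item.attributes)}


def default_catalog() -> ItemCatalog:
    """Ten guidance items spanning the two catalog categories."""
    S, L = "sleep_schedule_adjustment", "lifestyle_activity_optimization"
    return ItemCatalog([
        CatalogItem("bedtime_shift_30", S,
                    "Go to bed {shift} min earlier than usual.",
                    {"shift": 30}, (1.0, 0.0, 0.2)),
        CatalogItem("bedtime_shift_15", S,
                    "Go to bed {shift} min earlier than usual.",
                    {"shift": 15}, (0.8, 0.0, 0.1)),
        CatalogItem("wake_consistency", S,
                    "Keep your wake-up time within {window} min every day.",
                    {"window": 30}, (0.9, 0.1, 0.2)),
        CatalogItem("nap_limit", S,
                    "Limit daytime naps to {minutes} min before {cutoff}.",
                    {"minutes": 20, "cutoff": "15:00"}, (0.7, 0.2, 0.1)),
        CatalogItem("afternoon_walk", L,
                    "Take a {minutes}-min afternoon walk.",
                    {"minutes": 20}, (0.1, 1.0, 0.3)),
        CatalogItem("morning_exercise", L,
                    "Do {minutes} min of light exercise in the morning.",
                    {"minutes": 30}, (0.2, 0.9, 0.2)),
        CatalogItem("relaxation_breathing", L,
                    "Practice {minutes} min of breathing relaxation before bed.",
                    {"minutes": 10}, (0.0, 0.2, 1.0)),
        CatalogItem("stress_break", L,
                    "Schedule a short stress-management break during the day.",
                    {}, (0.0, 0.1, 0.9)),
        CatalogItem("room_dark", L,
                    "Darken the bedroom before sleep.",
                    {}, (0.3, 0.0, 0.6)),
        CatalogItem("room_quiet", L,
                    "Reduce bedroom noise exposure and adjust the temperature.",
                    {}, (0.2, 0.0, 0.7)),
    ])


def cosine_sim(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity; a zero vector yields 0 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("cosine similarity of a zero vector defined as 0")
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def cbsur(
    user_id: str,
    feature_vectors: pd.DataFrame,
    quality: pd.Series,
    clusters: pd.Series,
) -> str | None:
    """Best same-cluster, higher-quality reference user, or None.

    ``clusters`` uses -1 for unclustered/ambiguous users; an unclustered
    target falls back to the global candidate pool with a warning.
    """
    if user_id not in feature_vectors.index:
        raise KeyError(f"no feature vector for {user_id}")
    cu = clusters.get(user_id, -1)
    if cu == -1:
        warnings.warn(f"user {user_id} unclustered: falling back to global pool")
        pool = clusters.index
    else:
        pool = clusters.index[clusters == cu]
    candidates = [
        v for v in pool
        if v != user_id and v in feature_vectors.index
        and quality.get(v, -np.inf) > quality[user_id]
    ]
    if not candidates:
        return None
    x = feature_vectors.loc[user_id].to_numpy()
    sims = {v: cosine_sim(x, feature_vectors.loc[v].to_numpy()) for v in candidates}
    return max(sorted(sims), key=lambda v: sims[v])


class PFRARecommender(BaseEstimator):
    """Similarity-weighted neighbourhood rating prediction (user-based CF).

    Parameters
    ----------
    k_neighbors : neighbourhood size K.
    k_items : length of the recommendation list.
    restrict_to_cluster : keep neighbourhoods inside the user's cluster,
        falling back to the global pool when the cluster has fewer than
        ``k_neighbors`` other members (or the user is unclustered).  With
        False this is the plain user-based CF baseline.
    similarity : "features" computes cosine similarity between profile
        feature vectors; "ratings" between mean-centred rating vectors on
        co-rated items (the classic CF choice, used by the baseline).

    Fitted attributes: ``ratings_`` (users x items, night-aggregated),
    ``similarity_`` (users x users), ``item_means_``.
    """

    def __init__(self, k_neighbors: int = 10, k_items: int = 5,
                 restrict_to_cluster: bool = True, similarity: str = "features"):
        self.k_neighbors = k_neighbors
        self.k_items = k_items
        self.restrict_to_cluster = restrict_to_cluster
        self.similarity = similarity

    def fit(self, ratings: pd.DataFrame,
            feature_vectors: pd.DataFrame | None = None,
            clusters: pd.Series | None = None) -> "PFRARecommender":
        """``ratings``: users x items with NaN for unrated pairs."""
        self.ratings_ = ratings.copy()
        self.clusters_ = clusters
        users = ratings.index
        if self.similarity == "features":
            if feature_vectors is None:
                raise ValueError("feature similarity requires feature_vectors")
            common = [u for u in users if u in feature_vectors.index]
            F = feature_vectors.loc[common].to_numpy(dtype=float)
            norms = np.linalg.norm(F, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            S = (F / norms) @ (F / norms).T
            self.similarity_ = pd.DataFrame(S, index=common, columns=common).reindex(
                index=users, columns=users)
        elif self.similarity == "ratings":
            centred = ratings.sub(ratings.mean(axis=1), axis=0)
            filled = centred.fillna(0.0).to_numpy()
            norms = np.linalg.norm(filled, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            S = (filled / norms) @ (filled / norms).T
            self.similarity_ = pd.DataFrame(S, index=users, columns=users)
        else:
            raise ValueError(f"unknown similarity kind {self.similarity!r}")
        self.item_means_ = ratings.mean(axis=0)
        return self

    def neighborhood(self, user_id: str) -> pd.Series:
        """Top-K most similar users (descending, self and negatives excluded)."""
        sims = self.similarity_.loc[user_id].drop(user_id).dropna()
        if self.restrict_to_cluster and self.clusters_ is not None:
            cu = self.clusters_.get(user_id, -1)
            if cu != -1:
                members = set(self.clusters_.index[self.clusters_ == cu])
                in_cluster = sims[sims.index.isin(members)]
                if len(in_cluster) >= self.k_neighbors:
                    sims = in_cluster
                # else: cluster too small -> global fallback
        sims = sims[sims > 0]
        return sims.sort_values(ascending=False).head(self.k_neighbors)

    def predict(self, user_id: str, item_id: str) -> tuple[float, bool]:
        """Predicted rating and a flag marking the item-mean fallback."""
        neigh = self.neighborhood(user_id)
        rated = self.ratings_.loc[neigh.index, item_id].dropna()
        if rated.empty or neigh[rated.index].sum() == 0:
            return float(self.item_means_[item_id]), True
        w = neigh[rated.index]
        return float((w * rated).sum() / w.sum()), False

    def top_k(self, user_id: str, k_items: int | None = None) -> pd.DataFrame:
        """Unrated items ranked by predicted rating (ties by item id).

        Returns a DataFrame (item_id, score, fallback); empty with a
        warning when the user has rated everything.
        """
        k = self.k_items if k_items is None else k_items
        unrated = [i for i in self.ratings_.columns
                   if pd.isna(self.ratings_.at[user_id, i])] \
            if user_id in self.ratings_.index else list(self.ratings_.columns)
        if not unrated:
            warnings.warn(f"user {user_id} has rated every catalog item")
            return pd.DataFrame(columns=["item_id", "score", "fallback"])
        preds = [(i, *self.predict(user_id, i)) for i in unrated]
        df = pd.DataFrame(preds, columns=["item_id", "score", "fallback"])
        df = df.sort_values(["score", "item_id"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        return df.head(k)


def render_recommendation(item: CatalogItem, context: dict | None = None) -> dict:
    """Context-conditioned guidance record for one catalog item.

    Triggers: positive sleep debt selects the full 30-min earlier bedtime;
    a step count under the activity threshold selects the 20-min walk; a
    high stress index selects relaxation guidance; elevated night light or
    noise selects environment adjustments.  With no trigger active the
    template renders with default parameters and generic phrasing.
    """
    ctx = context or {}
    params = dict(item.params)
    triggers: list[str] = []
    if item.item_id.startswith("bedtime_shift") and ctx.get("sleep_debt", 0) > 0:
        params["shift"] = 30  # accumulated debt: advise the full advance
        triggers.append("sleep_debt")
    if item.item_id == "afternoon_walk" and \
            ctx.get("steps", np.inf) < ctx.get("steps_threshold", 7000):
        params["minutes"] = 20
        triggers.append("low_steps")
    if item.item_id in ("relaxation_breathing", "stress_break") and \
            ctx.get("stress", 0) >= ctx.get("stress_threshold", 60):
        triggers.append("high_stress")
    if item.item_id in ("room_dark", "room_quiet") and (
            ctx.get("light", 0) >= ctx.get("light_threshold", 20)
            or ctx.get("noise", 0) >= ctx.get("noise_threshold", 45)):
        triggers.append("night_environment")

    try:
        text = item.template.format(**params)
    except (KeyError, IndexError):
        text = item.template
    return {"item_id": item.item_id, "category": item.category,
            "text": text, "params": params, "triggers": triggers}
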