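"""Ranking metrics, the user-grouped split, and the ablation harness.

Metrics follow the standard top-K recommendation protocol:

* P@k  = (#relevant in the top k) / k
* AP   = mean of P@k over the ranks k holding relevant items
         (a list with zero relevant items is assigned AP 0 and flagged;
         flagged users are excluded from the mAP average)
* mAP  = unweighted mean of per-user APs
* F1   = harmonic mean of the top-K precision and recall

An item is *relevant* to a user when their night-aggregated rating reaches
``relevance_threshold`` (default 4 on the 1-5 scale).

``run_experiment`` reproduces the comparison grid of an ablation study on
a synthetic cohort: the full pipeline (MLP fused with feedback re-ranking)
against the no-re-ranking variant and classic baselines (user CF,
content-based filtering, and their equal-weight hybrid), each reported as
mean +- SD of mAP and F1 over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import profiles as prof
from .cluster import ClusterRefiner, user_cluster_table
from .cohort import Cohort, CohortSpec, LatentTruth, generate_cohort, rating_matrix
from .ranker import MLPRanker, TrainConfig, fuse_scores
from .recommend import ItemCatalog, PFRARecommender, default_catalog

__all__ = [
    "precision_at_k",
    "average_precision",
    "mean_ap",
    "f1_score",
    "grouped_split",
    "ExperimentConfig",
    "run_experiment",
]


def precision_at_k(relevance: np.ndarray, k: int) -> float:
    """Fraction of the top-k list that is relevant."""
    rel = np.asarray(relevance).astype(bool)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > rel.size:
        raise ValueError(f"k={k} exceeds list length {rel.size}")
    return float(rel[:k].sum() / k)


def average_precision(relevance: np.ndarray) -> tuple[float, bool]:
    """AP of one ranked list; returns (value, had_relevant).

    AP = (1/R) * sum_k P@k * rel_k over positions k, with rel_k the binary
    relevance indicator and R the number of relevant items.  With R = 0 the
    value is defined as 0 and the flag is False so callers can exclude the
    list from averaging.
    """
    rel = np.asarray(relevance).astype(bool)
    if not rel.any():
        return 0.0, False
    ranks = np.flatnonzero(rel) + 1
    precisions = [precision_at_k(rel, int(k)) for k in ranks]
    return float(np.mean(precisions)), True


def mean_ap(per_user_relevance: list[np.ndarray]) -> float:
    """Unweighted mean of per-user APs (zero-relevant users excluded)."""
    aps = []
    for rel in per_user_relevance:
        ap, ok = average_precision(rel)
        if ok:
            aps.append(ap)
    if not aps:
        raise ValueError("no user with a relevant item")
    return float(np.mean(aps))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean; defined as 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def grouped_split(
    user_ids,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """User-disjoint train/validation/test assignment (70/10/20 default).

    Splitting is by *user* so no user's nights leak across sets; within a
    user, nights stay in chronological order because the split never
    touches the night tables.  Counts are exact to rounding: train gets
    round(n*f_train), validation round(n*f_val), test the remainder.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    users = np.asarray(list(user_ids))
    if users.size < 10:
        raise ValueError("need at least 10 users for a grouped split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(users.size)
    n_train = int(round(users.size * fractions[0]))
    n_val = int(round(users.size * fractions[1]))
    train = users[order[:n_train]]
    val = users[order[n_train:n_train + n_val]]
    test = users[order[n_train + n_val:]]
    return np.sort(train), np.sort(val), np.sort(test)


# ---------------------------------------------------------------------------
# Experiment harness


@dataclass
class ExperimentConfig:
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    seeds: tuple[int, ...] = (0, 1, 2)
    k_items: int = 5
    k_neighbors: int = 10
    relevance_threshold: float = 4.0
    fusion_alpha: float = 0.5
    observed_fraction: float = 0.5  # share of a test user's items revealed
    train_config: TrainConfig = field(default_factory=lambda: TrainConfig(max_epochs=30))
    variants: tuple[str, ...] = ("full", "no_pfra", "cf", "cbf", "hybrid")


def _cbf_scores(user_obs: pd.Series, attrs: pd.DataFrame,
                candidates: list[str], threshold: float) -> np.ndarray:
    """Content-based scores: cosine(item attrs, liked-item centroid)."""
    liked = user_obs[user_obs >= threshold].index
    if len(liked) == 0:
        liked = user_obs.dropna().index  # no liked item: fall back to all rated
    if len(liked) == 0:
        return np.zeros(len(candidates))
    centroid = attrs.loc[liked].mean(axis=0).to_numpy()
    out = np.empty(len(candidates))
    for j, i in enumerate(candidates):
        a = attrs.loc[i].to_numpy()
        na, nc = np.linalg.norm(a), np.linalg.norm(centroid)
        out[j] = 0.0 if na == 0 or nc == 0 else float(a @ centroid / (na * nc))
    return out


def _rank(scores: np.ndarray, candidates: list[str]) -> list[str]:
    """Descending by score, ties by ascending item id."""
    order = sorted(range(len(candidates)), key=lambda j: (-scores[j], candidates[j]))
    return [candidates[j] for j in order]


def _evaluate_lists(lists: dict[str, list[str]], truth_rel: dict[str, set],
                    k: int) -> tuple[float, float]:
    """(mAP, mean F1) of per-user rankings against relevant-item sets."""
    rels, f1s = [], []
    for u, ranked in lists.items():
        rel_items = truth_rel[u]
        rel_flags = np.array([i in rel_items for i in ranked])
        if rel_flags.any():
            rels.append(rel_flags[:k])
            topk = set(ranked[:k])
            tp = len(topk & rel_items)
            p = tp / k
            r = tp / len(rel_items)
            f1s.append(f1_score(p, r))
    if not rels:
        return float("nan"), float("nan")
    return mean_ap(rels), float(np.mean(f1s))


def _build_training_arrays(features: pd.DataFrame, R: pd.DataFrame,
                           item_index: dict[str, int], users: np.ndarray,
                           fatigue_z: pd.Series, threshold: float,
                           rng: np.random.Generator):
    """(X, pairs, fatigue) rows: one per (user-night, pos, neg) sample."""
    X_rows, pair_rows, fat_rows = [], [], []
    feat_users = features.index.get_level_values("user_id")
    for u in users:
        if u not in R.index:
            continue
        r_u = R.loc[u]
        pos_items = [i for i in R.columns if r_u.get(i, np.nan) >= threshold]
        neg_items = [i for i in R.columns
                     if pd.isna(r_u.get(i, np.nan)) or r_u.get(i) <= 2]
        if not pos_items or not neg_items:
            continue
        nights_u = features[feat_users == u]
        take = nights_u.sample(n=min(6, len(nights_u)),
                               random_state=int(rng.integers(2 ** 31)))
        for (_, night), row in take.iterrows():
            pos = pos_items[int(rng.integers(len(pos_items)))]
            neg = neg_items[int(rng.integers(len(neg_items)))]
            X_rows.append(row.to_numpy(dtype=float))
            pair_rows.append((item_index[pos], item_index[neg]))
            fat_rows.append(fatigue_z.get((u, night), 0.0))
    if not X_rows:
        raise ValueError("no (positive, negative) training pairs could be built")
    return np.array(X_rows), np.array(pair_rows), np.array(fat_rows)


def run_experiment(config: ExperimentConfig,
                   cohort: Cohort | None = None,
                   truth: LatentTruth | None = None,
                   catalog: ItemCatalog | None = None) -> pd.DataFrame:
    """Ablation/baseline grid: variants x {mAP, F1}, mean +- SD over seeds.

    Per seed: generate (or reuse) a cohort, clean it, build features,
    cluster users, fit the feedback re-ranker and the MLP ranker on
    training users, then rank each test user's non-observed items under
    every variant and measure mAP/F1 at ``k_items``.
    """
    catalog = catalog or default_catalog()
    rows = []
    for seed in config.seeds:
        if cohort is None:
            spec = config.cohort_spec
            spec = CohortSpec(**{**spec.__dict__, "seed": seed})
            c, t = generate_cohort(spec, catalog)
        else:
            c, t = cohort.copy(), truth
        res = _run_single(config, c, catalog, seed)
        for variant, (m, f) in res.items():
            rows.append({"variant": variant, "seed": seed, "mAP": m, "F1": f})
    df = pd.DataFrame(rows)
    report = df.groupby("variant")[["mAP", "F1"]].agg(["mean", "std"])
    report.columns = ["_".join(col) for col in report.columns]
    return report.reindex(list(config.variants))


def _run_single(config: ExperimentConfig, cohort: Cohort,
                catalog: ItemCatalog, seed: int) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed)
    clean, _ = prof.clean_cohort(cohort)
    nights, users = clean.nights, clean.users

    train_u, val_u, test_u = grouped_split(users["user_id"], seed=seed)

    builder = prof.NightFeatureBuilder()
    builder.fit(nights[nights["user_id"].isin(train_u)],
                users[users["user_id"].isin(train_u)])
    features = builder.transform(nights, users)
    user_vecs = prof.user_feature_vectors(features)
    quality = prof.quality_scores(nights)

    refiner = ClusterRefiner(random_state=42)
    refiner.fit(user_cluster_table(nights))
    clusters = pd.Series(refiner.labels_, index=refiner.index_, name="cluster")

    R_full = rating_matrix(clean.ratings)
    item_index = {i: j for j, i in enumerate(catalog.ids)}
    attrs = catalog.attribute_matrix()
    thr = config.relevance_threshold

    # Test users: reveal half their rated items, evaluate on the rest.
    observed = R_full.copy()
    heldout_rel: dict[str, set] = {}
    candidates: dict[str, list[str]] = {}
    for u in test_u:
        if u not in R_full.index:
            continue
        rated = R_full.loc[u].dropna().index.to_numpy()
        rng_u = np.random.default_rng(seed * 100003 + hash(u) % 100003)
        n_obs = int(round(len(rated) * config.observed_fraction))
        obs_items = set(rng_u.choice(rated, size=n_obs, replace=False))
        hidden = [i for i in rated if i not in obs_items]
        observed.loc[u, hidden] = np.nan
        cands = [i for i in catalog.ids if i not in obs_items]
        candidates[u] = cands
        heldout_rel[u] = {i for i in hidden if R_full.at[u, i] >= thr}
    eval_users = [u for u in candidates if heldout_rel[u]]

    pfra = PFRARecommender(config.k_neighbors, config.k_items,
                           restrict_to_cluster=True, similarity="features")
    pfra.fit(observed, user_vecs, clusters)
    cf = PFRARecommender(config.k_neighbors, config.k_items,
                         restrict_to_cluster=False, similarity="ratings")
    cf.fit(observed)

    # MLP ranker trained on training users' feedback.
    fatigue_next = (nights.sort_values(["user_id", "night"])
                    .groupby("user_id")["fatigue"].shift(-1))
    fat_mu, fat_sd = fatigue_next.mean(), fatigue_next.std(ddof=0) or 1.0
    fatigue_z = pd.Series(
        ((fatigue_next - fat_mu) / fat_sd).fillna(0.0).to_numpy(),
        index=pd.MultiIndex.from_frame(
            nights.sort_values(["user_id", "night"])[["user_id", "night"]]),
    )
    X, pairs, fat = _build_training_arrays(
        features, R_full, item_index, train_u, fatigue_z, thr, rng)
    Xv, pv, fv = _build_training_arrays(
        features, R_full, item_index, val_u, fatigue_z, thr, rng)
    ranker = MLPRanker(n_items=len(catalog), config=config.train_config, seed=seed)
    ranker.fit(X, pairs, fat, Xv, pv, fv)

    variant_lists: dict[str, dict[str, list[str]]] = {
        v: {} for v in config.variants}
    for u in eval_users:
        cands = candidates[u]
        cidx = np.array([item_index[i] for i in cands])
        mlp_s = ranker.score_items(user_vecs.loc[u].to_numpy(), cidx)
        pfra_s = np.array([pfra.predict(u, i)[0] for i in cands])
        cf_s = np.array([cf.predict(u, i)[0] for i in cands])
        cbf_s = _cbf_scores(observed.loc[u], attrs, cands, thr)
        for v in config.variants:
            if v == "full":
                s = fuse_scores(mlp_s, pfra_s, config.fusion_alpha)
            elif v == "no_pfra":
                s = mlp_s
            elif v == "cf":
                s = cf_s
            elif v == "cbf":
                s = cbf_s
            elif v == "hybrid":
                s = fuse_scores(cbf_s, cf_s, 0.5)
            else:
                raise ValueError(f"unknown variant {v!r}")
            variant_lists[v][u] = _rank(s, cands)

    return {v: _evaluate_lists(variant_lists[v], heldout_rel, config.k_items)
            for v in config.variants}
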