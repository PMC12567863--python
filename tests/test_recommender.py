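"""CBSUR matching, PFRA prediction/ranking, catalog rendering."""

import numpy as np
import pandas as pd
import pytest

from sleeprec.recommend import (
    ItemCatalog,
    PFRARecommender,
    cbsur,
    cosine_sim,
    default_catalog,
    render_recommendation,
)


class TestCosine:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, 2.0, -1.0])
        assert cosine_sim(x, x) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # (1,2,3)·(3,2,1) = 10; norms sqrt(14) each -> 10/14
        assert cosine_sim([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14)

    def test_zero_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero vector"):
            assert cosine_sim([0, 0], [1, 1]) == 0.0

    def test_symmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert cosine_sim(x, y) == pytest.approx(cosine_sim(y, x))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_sim([1, 2], [1, 2, 3])


def _profile_fixture():
    vecs = pd.DataFrame(
        {"a": [1.0, 0.0], "b": [0.9, 0.1], "c": [0.0, 1.0],
         "d": [0.8, 0.2], "e": [1.0, 0.05]}).T
    quality = pd.Series({"a": 0.0, "b": 0.5, "c": 0.9, "d": -0.2, "e": 0.7})
    clusters = pd.Series({"a": 0, "b": 0, "c": 1, "d": 0, "e": 0})
    return vecs, quality, clusters


class TestCBSUR:
    def test_top_quality_user_gets_none(self):
        vecs, quality, clusters = _profile_fixture()
        quality["a"] = 5.0
        assert cbsur("a", vecs, quality, clusters) is None

    def test_single_eligible_candidate_returned(self):
        vecs, quality, clusters = _profile_fixture()
        clusters = pd.Series({"a": 0, "b": 0, "c": 1, "d": 1, "e": 1})
        assert cbsur("a", vecs, quality, clusters) == "b"

    def test_matches_brute_force_argmax(self, rng):
        ids = [f"u{i}" for i in range(6)]
        vecs = pd.DataFrame(rng.normal(size=(6, 4)), index=ids)
        quality = pd.Series(rng.normal(size=6), index=ids)
        clusters = pd.Series(0, index=ids)
        got = cbsur("u0", vecs, quality, clusters)
        eligible = [u for u in ids[1:] if quality[u] > quality["u0"]]
        if not eligible:
            assert got is None
        else:
            sims = {u: cosine_sim(vecs.loc["u0"], vecs.loc[u]) for u in eligible}
            assert got == max(sorted(sims), key=lambda u: sims[u])

    def test_never_crosses_cluster_or_quality(self):
        vecs, quality, clusters = _profile_fixture()
        ref = cbsur("a", vecs, quality, clusters)
        assert clusters[ref] == clusters["a"]
        assert quality[ref] > quality["a"]

    def test_unclustered_user_falls_back_to_global_pool(self):
        vecs, quality, clusters = _profile_fixture()
        clusters["a"] = -1
        with pytest.warns(UserWarning, match="unclustered"):
            ref = cbsur("a", vecs, quality, clusters)
        assert ref is not None


def _rating_fixture():
    """3 neighbours of u0 with controlled similarities via feature vectors."""
    R = pd.DataFrame(
        [[np.nan, np.nan], [5.0, 4.0], [3.0, np.nan], [1.0, 2.0]],
        index=["u0", "n1", "n2", "n3"], columns=["i1", "i2"],
    )
    return R


class TestPFRAPredict:
    def _fit(self, R, sims):
        rec = PFRARecommender(k_neighbors=10, restrict_to_cluster=False)
        rec.ratings_ = R
        rec.clusters_ = None
        users = R.index
        S = pd.DataFrame(np.eye(len(users)), index=users, columns=users)
        for (u, v), s in sims.items():
            S.loc[u, v] = S.loc[v, u] = s
        rec.similarity_ = S
        rec.item_means_ = R.mean(axis=0)
        return rec

    def test_symmetric_neighbours_average(self):
        R = pd.DataFrame([[np.nan], [4.0], [2.0]],
                         index=["u", "v", "w"], columns=["i"])
        rec = self._fit(R, {("u", "v"): 0.5, ("u", "w"): 0.5})
        pred, fallback = rec.predict("u", "i")
        assert pred == pytest.approx(3.0) and not fallback

    def test_single_neighbour_passthrough(self):
        R = pd.DataFrame([[np.nan], [5.0]], index=["u", "v"], columns=["i"])
        rec = self._fit(R, {("u", "v"): 0.7})
        assert rec.predict("u", "i")[0] == pytest.approx(5.0)

    def test_hand_computed_weighted_mean(self):
        R = pd.DataFrame([[np.nan], [5.0], [3.0], [1.0]],
                         index=["u", "a", "b", "c"], columns=["i"])
        rec = self._fit(R, {("u", "a"): 0.9, ("u", "b"): 0.3, ("u", "c"): 0.1})
        # (0.9*5 + 0.3*3 + 0.1*1) / 1.3 = 5.5/1.3
        assert rec.predict("u", "i")[0] == pytest.approx(5.5 / 1.3)

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Formula oracle: 1000 random queries on 20x10 matrices."""
        n_u, n_i, K = 20, 10, 5
        users = [f"u{i}" for i in range(n_u)]
        items = [f"i{j}" for j in range(n_i)]
        R = pd.DataFrame(rng.integers(1, 6, size=(n_u, n_i)).astype(float),
                         index=users, columns=items)
        R[rng.random((n_u, n_i)) < 0.4] = np.nan
        vecs = pd.DataFrame(rng.normal(size=(n_u, 6)), index=users)
        rec = PFRARecommender(k_neighbors=K, restrict_to_cluster=False)
        rec.fit(R, vecs)
        for _ in range(1000):
            u = users[rng.integers(n_u)]
            i = items[rng.integers(n_i)]
            pred, fallback = rec.predict(u, i)
            # brute force: cosine sims, positive only, top-K, weighted mean
            sims = {v: cosine_sim(vecs.loc[u], vecs.loc[v])
                    for v in users if v != u}
            pos = {v: s for v, s in sims.items() if s > 0}
            top = sorted(pos, key=lambda v: -pos[v])[:K]
            contrib = [(pos[v], R.at[v, i]) for v in top if not np.isnan(R.at[v, i])]
            if not contrib or sum(w for w, _ in contrib) == 0:
                assert fallback
                assert pred == pytest.approx(R[i].mean())
            else:
                expected = (sum(w * r for w, r in contrib)
                            / sum(w for w, _ in contrib))
                assert pred == pytest.approx(expected, abs=1e-12)

    def test_prediction_is_convex_combination(self, rng):
        n_u, n_i = 15, 8
        users = [f"u{i}" for i in range(n_u)]
        R = pd.DataFrame(rng.integers(1, 6, size=(n_u, n_i)).astype(float),
                         index=users, columns=[f"i{j}" for j in range(n_i)])
        vecs = pd.DataFrame(np.abs(rng.normal(size=(n_u, 4))), index=users)
        rec = PFRARecommender(k_neighbors=5, restrict_to_cluster=False).fit(R, vecs)
        for u in users[:5]:
            neigh = rec.neighborhood(u)
            for i in R.columns[:4]:
                pred, fb = rec.predict(u, i)
                if not fb:
                    rated = R.loc[neigh.index, i].dropna()
                    assert rated.min() - 1e-9 <= pred <= rated.max() + 1e-9

    def test_shift_equivariance(self):
        R = pd.DataFrame([[np.nan], [4.0], [2.0]],
                         index=["u", "v", "w"], columns=["i"])
        rec = self._fit(R, {("u", "v"): 0.8, ("u", "w"): 0.4})
        base = rec.predict("u", "i")[0]
        rec2 = self._fit(R + 1.0, {("u", "v"): 0.8, ("u", "w"): 0.4})
        assert rec2.predict("u", "i")[0] == pytest.approx(base + 1.0)

    def test_no_neighbour_rating_falls_back_to_item_mean(self):
        R = pd.DataFrame([[np.nan, 3.0], [np.nan, 4.0]],
                         index=["u", "v"], columns=["i1", "i2"])
        rec = self._fit(R, {("u", "v"): 0.9})
        pred, fallback = rec.predict("u", "i1")
        assert fallback and np.isnan(pred) or fallback  # i1 has no ratings at all
        pred2, fb2 = rec.predict("u", "i2")
        assert not fb2


class TestPFRATopK:
    def test_equal_predictions_ordered_by_item_id(self):
        R = pd.DataFrame([[np.nan, np.nan, np.nan], [3.0, 3.0, 3.0]],
                         index=["u", "v"], columns=["c", "a", "b"])
        vecs = pd.DataFrame([[1.0], [1.0]], index=["u", "v"])
        rec = PFRARecommender(k_neighbors=5, restrict_to_cluster=False).fit(R, vecs)
        out = rec.top_k("u", 3)
        assert out["item_id"].tolist() == ["a", "b", "c"]

    def test_dominant_item_ranks_first(self):
        R = pd.DataFrame([[np.nan, np.nan], [5.0, 2.0]],
                         index=["u", "v"], columns=["best", "worst"])
        vecs = pd.DataFrame([[1.0], [1.0]], index=["u", "v"])
        rec = PFRARecommender(restrict_to_cluster=False).fit(R, vecs)
        assert rec.top_k("u", 2)["item_id"].iloc[0] == "best"

    def test_matches_full_sort_oracle(self, rng):
        users = [f"u{i}" for i in range(8)]
        items = [f"i{j}" for j in range(6)]
        R = pd.DataFrame(rng.integers(1, 6, size=(8, 6)).astype(float),
                         index=users, columns=items)
        R.loc["u0"] = np.nan
        vecs = pd.DataFrame(np.abs(rng.normal(size=(8, 3))), index=users)
        rec = PFRARecommender(k_neighbors=4, restrict_to_cluster=False).fit(R, vecs)
        out = rec.top_k("u0", 6)
        preds = {i: rec.predict("u0", i)[0] for i in items}
        expected = sorted(items, key=lambda i: (-preds[i], i))
        assert out["item_id"].tolist() == expected

    def test_everything_rated_returns_empty_with_notice(self):
        R = pd.DataFrame([[3.0, 4.0], [2.0, 5.0]],
                         index=["u", "v"], columns=["i1", "i2"])
        vecs = pd.DataFrame([[1.0], [1.0]], index=["u", "v"])
        rec = PFRARecommender(restrict_to_cluster=False).fit(R, vecs)
        with pytest.warns(UserWarning, match="rated every"):
            out = rec.top_k("u")
        assert out.empty

    def test_cluster_restriction_limits_neighbourhood(self):
        users = [f"u{i}" for i in range(6)]
        R = pd.DataFrame(np.full((6, 2), 3.0), index=users,
                         columns=["i1", "i2"])
        R.loc["u0"] = np.nan
        vecs = pd.DataFrame(np.ones((6, 2)), index=users)
        clusters = pd.Series([0, 0, 0, 1, 1, 1], index=users)
        rec = PFRARecommender(k_neighbors=2, restrict_to_cluster=True)
        rec.fit(R, vecs, clusters)
        assert set(rec.neighborhood("u0").index) <= {"u1", "u2"}


class TestCatalogAndRendering:
    def test_default_catalog_valid_and_two_categories(self, catalog):
        cats = {it.category for it in catalog.items}
        assert cats == {"sleep_schedule_adjustment",
                        "lifestyle_activity_optimization"}
        assert len(catalog.ids) == len(set(catalog.ids))

    def test_duplicate_ids_rejected(self, catalog):
        items = catalog.items + [catalog.items[0]]
        with pytest.raises(ValueError, match="duplicate"):
            ItemCatalog(items)

    def test_sleep_debt_triggers_30min_earlier_bedtime(self, catalog):
        rec = render_recommendation(catalog["bedtime_shift_30"],
                                    {"sleep_debt": 120.0})
        assert rec["params"]["shift"] == 30
        assert "sleep_debt" in rec["triggers"]
        assert "30 min earlier" in rec["text"]

    def test_low_steps_triggers_20min_walk(self, catalog):
        rec = render_recommendation(catalog["afternoon_walk"],
                                    {"steps": 3000})
        assert rec["params"]["minutes"] == 20
        assert "low_steps" in rec["triggers"]
        assert "20-min afternoon walk" in rec["text"]

    def test_no_trigger_renders_defaults(self, catalog):
        rec = render_recommendation(catalog["afternoon_walk"], {})
        assert rec["triggers"] == []
        assert rec["params"] == {"minutes": 20}


def test_planted_preference_recovery_beats_random_ranking(catalog):
    """PFRA top-5 mAP beats random ranking by >= 0.15 on planted ratings."""
    from sleeprec.cohort import CohortSpec, generate_cohort, rating_matrix
    from sleeprec.evaluation import mean_ap
    from sleeprec.profiles import NightFeatureBuilder, clean_cohort, user_feature_vectors

    gains = []
    for seed in (0, 1, 2):
        spec = CohortSpec(n_users=50, n_nights=21, seed=seed, rating_noise_sd=0.5)
        cohort, truth = generate_cohort(spec, catalog)
        clean, _ = clean_cohort(cohort)
        R = rating_matrix(clean.ratings)
        b = NightFeatureBuilder().fit(clean.nights, clean.users)
        vecs = user_feature_vectors(b.transform(clean.nights, clean.users))
        util = truth.utilities
        rng = np.random.default_rng(seed)

        # hide half of each user's rated items; relevant = true utility >= 4
        observed = R.copy()
        hidden: dict[str, list] = {}
        for u in R.index:
            rated = R.loc[u].dropna().index.to_numpy()
            h = rng.choice(rated, size=len(rated) // 2, replace=False)
            observed.loc[u, h] = np.nan
            hidden[u] = list(h)
        rec = PFRARecommender(k_neighbors=10, restrict_to_cluster=False)
        rec.fit(observed, vecs)

        pfra_rel, rand_rel = [], []
        for u in R.index:
            cands = [i for i in catalog.ids
                     if pd.isna(observed.at[u, i])]
            rel_set = {i for i in hidden[u] if util.at[u, i] >= 4.0}
            if not rel_set:
                continue
            preds = {i: rec.predict(u, i)[0] for i in cands}
            ranked = sorted(cands, key=lambda i: (-preds[i], i))[:5]
            pfra_rel.append(np.array([i in rel_set for i in ranked]))
            shuffled = list(rng.permutation(cands))[:5]
            rand_rel.append(np.array([i in rel_set for i in shuffled]))
        gains.append(mean_ap(pfra_rel) - mean_ap(rand_rel))
    assert np.mean(gains) >= 0.15
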