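"""User profiling: cleaning, sleep metrics, activity categories, features.

The profiling stage turns raw nightly tables into the objects the
recommenders consume: a cleaned cohort (gap imputation, unusable-night
removal), per-user activity categories relative to cohort quartiles,
cumulative sleep debt, a per-user quality score from normalized nightly
ratings, and the fixed 68-component user-night feature vector that feeds
both the cosine-similarity matcher and the MLP ranker.

Feature schema (68 components, versioned as FEATURE_SCHEMA_VERSION):
  32  lagged history: {3,7}-night trailing mean and SD (previous nights
      only) of steps, hr_mean, hr_sd, stress, fatigue, tst, waso, efficiency
  12  current night: steps, hr_mean, hr_sd, stress, fatigue, tst, sol,
      waso, efficiency, time_in_bed, gap_minutes, prior-night rating
   8  bed features + their 7-night trailing means
   4  environment: temperature, humidity, light, noise
   1  cumulative sleep debt
   4  circadian sin/cos of bedtime and midsleep
   1  age
   2  sex one-hot
   4  activity-category one-hot (low/high/irregular/typical)
Continuous components are z-scored on training-user statistics; the
circadian pairs are already on the unit circle and stay raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import BED_CHANNELS, Cohort, WEARABLE_CHANNELS

__all__ = [
    "SleepAnnotations",
    "clean_cohort",
    "sleep_metrics",
    "categorize_activity",
    "sleep_debt",
    "quality_scores",
    "NightFeatureBuilder",
    "build_feature_vector",
    "user_feature_vectors",
    "circadian_encoding",
    "FEATURE_SCHEMA_VERSION",
]

FEATURE_SCHEMA_VERSION = "1"

_LAG_SIGNALS = ["steps", "hr_mean", "hr_sd", "stress", "fatigue", "tst", "waso", "efficiency"]
_CURRENT = ["steps", "hr_mean", "hr_sd", "stress", "fatigue", "tst", "sol", "waso",
            "efficiency", "time_in_bed", "gap_minutes"]
_BED = ["resp_rate", "posture_transitions", "micro_movement", "pressure_entropy"]
_ENV = ["temperature", "humidity", "light", "noise"]
_ACTIVITY_LEVELS = ["low", "high", "irregular", "typical"]
_SEX_LEVELS = ["F", "M"]


def feature_names() -> list[str]:
    names: list[str] = []
    for sig in _LAG_SIGNALS:
        for w in (3, 7):
            names += [f"{sig}_lag{w}_mean", f"{sig}_lag{w}_sd"]
    names += _CURRENT + ["prior_rating"]
    names += _BED + [f"{b}_lag7_mean" for b in _BED]
    names += _ENV
    names += ["sleep_debt"]
    names += ["bedtime_sin", "bedtime_cos", "midsleep_sin", "midsleep_cos"]
    names += ["age"]
    names += [f"sex_{s}" for s in _SEX_LEVELS]
    names += [f"activity_{a}" for a in _ACTIVITY_LEVELS]
    assert len(names) == 68
    return names


# ---------------------------------------------------------------------------
# Cleaning


def clean_cohort(cohort: Cohort, max_gap_minutes: float = 30.0) -> tuple[Cohort, pd.DataFrame]:
    """Impute short gaps, drop unusable nights, code unknown categories.

    * A night whose wearable block or bed block is entirely missing is
      removed.
    * A single missing channel value whose recorded gap is < ``max_gap_minutes``
      is imputed with the mean of the nearest valid values before and after
      (adjacent valid segments of the same user's series); gaps at or above
      the threshold make the night unusable.
    * Missing ``location_category`` entries become ``"unknown"``.

    Returns the cleaned cohort and a removal log (one row per dropped
    night).  A user losing every night is excluded with a warning.
    """
    out = cohort.copy()
    nights = out.nights
    removal: list[dict] = []

    wear_all_nan = nights[WEARABLE_CHANNELS].isna().all(axis=1)
    bed_all_nan = nights[BED_CHANNELS].isna().all(axis=1)
    partial_nan = nights[WEARABLE_CHANNELS + BED_CHANNELS].isna().any(axis=1)
    long_gap = partial_nan & ~wear_all_nan & ~bed_all_nan & (
        nights["gap_minutes"] >= max_gap_minutes
    )
    drop = wear_all_nan | bed_all_nan | long_gap
    for i in nights.index[drop]:
        reason = ("missing_wearable" if wear_all_nan[i]
                  else "missing_bed" if bed_all_nan[i] else "long_gap")
        removal.append({"user_id": nights.at[i, "user_id"],
                        "night": int(nights.at[i, "night"]), "reason": reason})
    nights = nights.loc[~drop].copy()

    # Short-gap imputation: nearest valid neighbours within the user series.
    for ch in WEARABLE_CHANNELS + BED_CHANNELS:
        if not nights[ch].isna().any():
            continue
        grp = nights.groupby("user_id", sort=False)[ch]
        prev_valid = grp.ffill()
        next_valid = grp.bfill()
        fill = pd.concat([prev_valid, next_valid], axis=1).mean(axis=1)
        nights[ch] = nights[ch].fillna(fill)

    nights["location_category"] = nights["location_category"].fillna("unknown")

    lost = set(out.users["user_id"]) - set(nights["user_id"])
    if lost:
        warnings.warn(f"users excluded after cleaning (no nights left): {sorted(lost)}")
        out.users = out.users[~out.users["user_id"].isin(lost)].copy()
    out.nights = nights.reset_index(drop=True)
    return out, pd.DataFrame(removal, columns=["user_id", "night", "reason"])


# ---------------------------------------------------------------------------
# Sleep metrics


@dataclass(frozen=True)
class SleepAnnotations:
    """Event annotations of one night, minutes on a common clock."""

    bed_entry: float
    sleep_onset: float
    final_wake: float
    rise: float | None = None  # leaving bed; defaults to final_wake
    awakenings: tuple[tuple[float, float], ...] = ()  # (start, end) pairs


def sleep_metrics(ann: SleepAnnotations) -> dict[str, float]:
    """TST / SOL / WASO / efficiency from event annotations.

    SOL = onset - bed entry; WASO = total awake minutes between onset and
    final wake; TST = (final wake - onset) - WASO; efficiency = TST / time
    in bed, with time in bed running from bed entry to rise.
    """
    if ann.sleep_onset < ann.bed_entry:
        raise ValueError("sleep onset precedes bed entry")
    if ann.final_wake < ann.sleep_onset:
        raise ValueError("final wake precedes sleep onset")
    rise = ann.final_wake if ann.rise is None else ann.rise
    waso = 0.0
    for start, end in ann.awakenings:
        if not ann.sleep_onset <= start <= end <= ann.final_wake:
            raise ValueError(f"awakening ({start}, {end}) outside the sleep period")
        waso += end - start
    sol = ann.sleep_onset - ann.bed_entry
    tst = (ann.final_wake - ann.sleep_onset) - waso
    tib = rise - ann.bed_entry
    if tib <= 0:
        raise ValueError("non-positive time in bed")
    return {"tst": tst, "sol": sol, "waso": waso, "efficiency": tst / tib,
            "time_in_bed": tib}


# ---------------------------------------------------------------------------
# Activity categories & sleep debt


def categorize_activity(
    nights: pd.DataFrame,
    min_days: int = 7,
    cv_percentile: float = 75.0,
) -> pd.Series:
    """Per-user activity category from cohort step statistics.

    low  = lowest quartile of mean daily steps; high = highest quartile;
    irregular = day-to-day step CV above the cohort ``cv_percentile``
    (precedence over low/high); everything else typical.
    """
    per_user = nights.groupby("user_id")["steps"]
    counts = per_user.count()
    if (counts < min_days).any():
        bad = counts[counts < min_days].index.tolist()
        raise ValueError(f"users with < {min_days} days of steps: {bad}")
    mean_steps = per_user.mean()
    cv = per_user.std(ddof=1) / mean_steps
    q25, q75 = np.quantile(mean_steps, [0.25, 0.75])
    cv_cut = np.percentile(cv.dropna(), cv_percentile)

    cat = pd.Series("typical", index=mean_steps.index, name="activity_category")
    cat[mean_steps <= q25] = "low"
    cat[mean_steps >= q75] = "high"
    cat[cv > cv_cut] = "irregular"  # precedence: irregular > low/high
    return cat


def sleep_debt(tst: np.ndarray | pd.Series, baseline_min: float = 480.0) -> np.ndarray:
    """Cumulative non-negative sleep shortfall.

    debt_t = max(0, debt_{t-1} + baseline - TST_t); a long night pays debt
    down but never banks credit.
    """
    if baseline_min <= 0:
        raise ValueError("baseline must be > 0")
    tst = np.asarray(tst, dtype=float)
    debt = np.empty_like(tst)
    d = 0.0
    for i, t in enumerate(tst):
        d = max(0.0, d + baseline_min - t)
        debt[i] = d
    return debt


def quality_scores(nights: pd.DataFrame) -> pd.Series:
    """Per-user aggregated quality: cohort-normalized nightly ratings, meaned.

    Nightly 1-5 ratings are z-scored against the cohort's grand mean/SD
    (normalizing the subjective scale) and averaged within user.
    """
    r = nights["rating"]
    mu, sd = r.mean(), r.std(ddof=0)
    z = (r - mu) / (sd if sd > 0 else 1.0)
    return z.groupby(nights["user_id"]).mean().rename("quality_score")


def circadian_encoding(minutes: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Clock time (minutes past midnight) onto the unit circle."""
    theta = 2 * np.pi * (np.asarray(minutes, dtype=float) % 1440.0) / 1440.0
    return np.sin(theta), np.cos(theta)


# ---------------------------------------------------------------------------
# Feature vectors


class NightFeatureBuilder(BaseEstimator, TransformerMixin):
    """Builds the 68-component user-night feature matrix.

    ``fit`` learns, from training users only, the z-scoring statistics of
    every continuous component plus the cohort step quartiles that define
    activity categories.  ``transform`` then maps any (users, nights) pair
    onto the fixed schema, so validation/test users are encoded with
    training statistics and no leakage occurs.

    Parameters
    ----------
    baseline_sleep_min : nightly sleep requirement for the debt recursion.
    """

    def __init__(self, baseline_sleep_min: float = 480.0):
        self.baseline_sleep_min = baseline_sleep_min

    def fit(self, nights: pd.DataFrame, users: pd.DataFrame) -> "NightFeatureBuilder":
        raw = self._raw_features(nights, users, activity=None)
        per_user = nights.groupby("user_id")["steps"]
        mean_steps = per_user.mean()
        self.step_q25_, self.step_q75_ = np.quantile(mean_steps, [0.25, 0.75])
        cv = (per_user.std(ddof=1) / mean_steps).dropna()
        self.cv_cut_ = float(np.percentile(cv, 75.0))
        self.activity_train_ = categorize_activity(nights)
        self.rating_fallback_ = float(nights["rating"].mean())

        cont = [c for c in raw.columns
                if not (c.startswith(("sex_", "activity_"))
                        or c.endswith(("_sin", "_cos")))]
        self.continuous_ = cont
        self.mean_ = raw[cont].mean()
        sd = raw[cont].std(ddof=0)
        self.scale_ = sd.where(sd > 0, 1.0)
        self.feature_names_ = feature_names()
        return self

    def transform(self, nights: pd.DataFrame, users: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise RuntimeError("NightFeatureBuilder is not fitted")
        activity = self._activity_for(nights)
        out = self._raw_features(nights, users, activity)
        out[self.continuous_] = (out[self.continuous_] - self.mean_) / self.scale_
        out = out[self.feature_names_]
        if not np.isfinite(out.to_numpy()).all():
            raise ValueError("non-finite feature components after preprocessing")
        return out

    def fit_transform(self, nights, users=None, **kw):  # noqa: D102 (sklearn signature)
        return self.fit(nights, users).transform(nights, users)

    # -- internals ----------------------------------------------------------

    def _activity_for(self, nights: pd.DataFrame) -> pd.Series:
        """Categories for possibly-unseen users via stored training cuts."""
        per_user = nights.groupby("user_id")["steps"]
        mean_steps = per_user.mean()
        cv = per_user.std(ddof=1) / mean_steps
        cat = pd.Series("typical", index=mean_steps.index)
        cat[mean_steps <= self.step_q25_] = "low"
        cat[mean_steps >= self.step_q75_] = "high"
        cat[cv > self.cv_cut_] = "irregular"
        return cat

    def _raw_features(self, nights: pd.DataFrame, users: pd.DataFrame,
                      activity: pd.Series | None) -> pd.DataFrame:
        df = nights.sort_values(["user_id", "night"]).reset_index(drop=True)
        g = df.groupby("user_id", sort=False)
        out = pd.DataFrame(index=df.index)
        out["user_id"] = df["user_id"]
        out["night"] = df["night"]

        for sig in _LAG_SIGNALS:
            shifted = g[sig].shift(1)
            for w in (3, 7):
                roll = shifted.groupby(df["user_id"]).rolling(w, min_periods=1)
                m = roll.mean().reset_index(level=0, drop=True)
                s = roll.std(ddof=0).reset_index(level=0, drop=True)
                out[f"{sig}_lag{w}_mean"] = m.fillna(df[sig])  # first night: no history
                out[f"{sig}_lag{w}_sd"] = s.fillna(0.0)

        for c in _CURRENT:
            out[c] = df[c]

        prior = g["rating"].shift(1)
        user_mean = df.groupby("user_id")["rating"].transform("mean")
        fallback = getattr(self, "rating_fallback_", df["rating"].mean())
        out["prior_rating"] = prior.fillna(user_mean).fillna(fallback)

        for b in _BED:
            out[b] = df[b]
            shifted = g[b].shift(1)
            roll = shifted.groupby(df["user_id"]).rolling(7, min_periods=1)
            out[f"{b}_lag7_mean"] = (
                roll.mean().reset_index(level=0, drop=True).fillna(df[b])
            )

        for c in _ENV:
            out[c] = df[c]

        out["sleep_debt"] = np.concatenate([
            sleep_debt(sub["tst"].to_numpy(), self.baseline_sleep_min)
            for _, sub in df.groupby("user_id", sort=False)
        ])

        bt_sin, bt_cos = circadian_encoding(df["bedtime_min"].to_numpy())
        out["bedtime_sin"], out["bedtime_cos"] = bt_sin, bt_cos
        midsleep = df["bedtime_min"] + df["sol"] + df["tst"] / 2.0
        ms_sin, ms_cos = circadian_encoding(midsleep.to_numpy())
        out["midsleep_sin"], out["midsleep_cos"] = ms_sin, ms_cos

        meta = users.set_index("user_id")
        out["age"] = df["user_id"].map(meta["age"]).astype(float)
        sex = df["user_id"].map(meta["sex"])
        unknown_sex = set(sex.dropna().unique()) - set(_SEX_LEVELS)
        if unknown_sex:
            raise ValueError(f"unknown sex category {unknown_sex}")
        for s in _SEX_LEVELS:
            out[f"sex_{s}"] = (sex == s).astype(float)

        if activity is None:
            activity = categorize_activity(df)
        act = df["user_id"].map(activity)
        for a in _ACTIVITY_LEVELS:
            out[f"activity_{a}"] = (act == a).astype(float)

        return out.set_index(["user_id", "night"])


def build_feature_vector(builder: NightFeatureBuilder, nights: pd.DataFrame,
                         users: pd.DataFrame, user_id: str, night: int) -> pd.Series:
    """One user-night's 68-component vector (thin convenience wrapper)."""
    sub = nights[nights["user_id"] == user_id]
    feats = builder.transform(sub, users[users["user_id"] == user_id])
    return feats.loc[(user_id, night)]


def user_feature_vectors(features: pd.DataFrame) -> pd.DataFrame:
    """Per-user profile vector: mean of the user's night feature vectors."""
    return features.groupby(level="user_id").mean()
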