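"""Synthetic lifelog cohort generator.

Emulates a 12-week wearable + smart-bed study of ~100 community-dwelling
adults: nightly wearable aggregates (steps, heart-rate statistics, HRV-proxy
stress and fatigue indices), bed-derived features, environment readings,
sleep outcomes (TST, SOL, WASO, efficiency), and 1-5 subjective sleep
ratings.  Users belong to one of three latent lifestyle groups patterned on
the profiles a silhouette analysis of such a cohort produces:

* group 0 — moderate stress, irregular activity (high day-to-day step CV)
* group 1 — high stress, low activity
* group 2 — low stress, high activity (best average sleep quality)

The generator also plants a low-rank user x item preference structure that
drives ratings of recommendation items, so collaborative-filtering stages
have a recoverable signal.  Ground truth (group labels, utility matrices,
per-night respiration rates, injected-missingness log) is returned in a
:class:`LatentTruth` object that downstream pipeline code never consumes —
it exists only so recovery tests can compare estimates against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GroupParams",
    "CohortSpec",
    "MissingnessSpec",
    "LatentTruth",
    "Cohort",
    "DEFAULT_GROUPS",
    "generate_population",
    "generate_ratings",
    "inject_missingness",
    "generate_cohort",
    "rating_matrix",
    "round_half_up",
    "save_cohort",
    "load_cohort",
]

# Nightly wearable/bed channels; all-NaN in a block => whole-night signal loss.
WEARABLE_CHANNELS = ["steps", "hr_mean", "hr_sd", "stress", "fatigue"]
BED_CHANNELS = ["resp_rate", "posture_transitions", "micro_movement", "pressure_entropy"]
ENV_CHANNELS = ["temperature", "humidity", "light", "noise"]


@dataclass(frozen=True)
class GroupParams:
    """Distribution parameters for one latent lifestyle group.

    Steps are Poisson-lognormal (a lognormal daily rate, then a Poisson
    draw), which gives positive, overdispersed counts; ``steps_log_sd``
    controls the day-to-day coefficient of variation, so an "irregular
    activity" group is simply one with a large value here.  Continuous
    physiology is Gaussian truncated at physical bounds.
    """

    name: str
    steps_log_mean: float
    steps_log_sd: float
    hr_mean: float
    hr_mean_sd: float
    hr_sd_mean: float
    stress_mean: float
    stress_sd: float
    fatigue_mean: float
    fatigue_sd: float
    quality_mean: float  # latent nightly sleep quality on the 1-5 rating scale
    quality_sd: float
    tst_mean: float  # minutes
    tst_sd: float
    pref: tuple[float, float, float] = (0.5, 0.5, 0.5)
    # Item-preference direction in the 3-d item attribute space
    # (schedule-regularity benefit, activity benefit, stress-relief benefit).


DEFAULT_GROUPS: tuple[GroupParams, ...] = (
    GroupParams(
        name="moderate_stress_irregular_activity",
        steps_log_mean=np.log(8000.0), steps_log_sd=0.55,
        hr_mean=72.0, hr_mean_sd=4.0, hr_sd_mean=9.0,
        stress_mean=55.0, stress_sd=9.0, fatigue_mean=52.0, fatigue_sd=9.0,
        quality_mean=3.9, quality_sd=0.55, tst_mean=420.0, tst_sd=35.0,
        pref=(1.0, 0.35, 0.5),
    ),
    GroupParams(
        name="high_stress_low_activity",
        steps_log_mean=np.log(3500.0), steps_log_sd=0.22,
        hr_mean=78.0, hr_mean_sd=4.0, hr_sd_mean=11.0,
        stress_mean=76.0, stress_sd=8.0, fatigue_mean=68.0, fatigue_sd=8.0,
        quality_mean=2.8, quality_sd=0.6, tst_mean=375.0, tst_sd=40.0,
        pref=(0.3, 0.85, 1.0),
    ),
    GroupParams(
        name="low_stress_high_activity",
        steps_log_mean=np.log(12500.0), steps_log_sd=0.18,
        hr_mean=64.0, hr_mean_sd=3.5, hr_sd_mean=7.0,
        stress_mean=30.0, stress_sd=8.0, fatigue_mean=36.0, fatigue_sd=8.0,
        quality_mean=4.4, quality_sd=0.45, tst_mean=450.0, tst_sd=30.0,
        pref=(0.6, 0.35, 0.2),
    ),
)


@dataclass(frozen=True)
class MissingnessSpec:
    """Rates of the three missingness mechanisms injected into a cohort.

    ``gap_rate``      – probability a user-night carries a short (<30 min)
                        recording gap in one wearable channel.
    ``drop_rate``     – probability an entire night loses its wearable or
                        bed signal block (the night is unusable).
    ``unknown_rate``  – probability a categorical entry is blanked.
    """

    gap_rate: float = 0.02
    drop_rate: float = 0.009
    unknown_rate: float = 0.01

    def validate(self) -> None:
        for name in ("gap_rate", "drop_rate", "unknown_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_users: int = 100
    n_nights: int = 84  # 12 weeks
    cluster_mixture: tuple[float, ...] = (0.2, 0.1, 0.7)
    groups: tuple[GroupParams, ...] = DEFAULT_GROUPS
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    rated_fraction: float = 0.8   # probability a user ever rates a given item
    rating_noise_sd: float = 0.5  # per-night noise added to item utility
    nightly_rating_rate: float = 0.85  # probability a night has a 1-5 rating
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 2:
            raise ValueError("n_users must be >= 2")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if len(self.cluster_mixture) != len(self.groups):
            raise ValueError("cluster_mixture length must match number of groups")
        mix = np.asarray(self.cluster_mixture, dtype=float)
        if np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-8):
            raise ValueError(
                f"cluster_mixture must be non-negative and sum to 1, got {tuple(mix)}"
            )
        for g in self.groups:
            if g.steps_log_sd <= 0 or g.quality_sd <= 0 or g.tst_sd <= 0:
                raise ValueError(f"group {g.name}: dispersions must be > 0")
        self.missingness.validate()


@dataclass
class LatentTruth:
    """Ground truth behind a generated cohort; consumed only by tests."""

    group: pd.Series  # user_id -> group index
    pref_vectors: pd.DataFrame  # user_id x 3 preference direction
    user_offset: pd.Series  # per-user rating offset
    utilities: pd.DataFrame | None = None  # user x item true utility
    resp_rate_hz: pd.Series | None = None  # (user_id, night) -> true breathing freq
    injections: pd.DataFrame | None = None  # missingness log

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group": self.group.to_dict(),
            "pref_vectors": self.pref_vectors.to_dict(orient="index"),
            "user_offset": self.user_offset.to_dict(),
            "utilities": None if self.utilities is None
            else self.utilities.to_dict(orient="index"),
            "resp_rate_hz": None if self.resp_rate_hz is None
            else {f"{u}|{n}": v for (u, n), v in self.resp_rate_hz.items()},
            "injections": None if self.injections is None
            else self.injections.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Cohort:
    """A generated study: per-user table, per-night table, long rating table."""

    users: pd.DataFrame
    nights: pd.DataFrame
    ratings: pd.DataFrame | None = None

    def copy(self) -> "Cohort":
        return Cohort(
            self.users.copy(),
            self.nights.copy(),
            None if self.ratings is None else self.ratings.copy(),
        )


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round halves away from zero-point-five upward (2.5 -> 3, 2.4 -> 2)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Gaussian draw truncated to [lo, hi] by resampling, clip as last resort."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(8):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
                              sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def generate_population(spec: CohortSpec) -> tuple[Cohort, LatentTruth]:
    """Draw users and their nightly observables from group-conditional laws.

    Deterministic for a fixed ``spec.seed``.  Nightly sleep quality is
    positively coupled to activity and negatively to stress both across
    groups (via group means) and within a user (via nightly z-scores), so a
    clustering of daytime behaviour is informative about sleep outcomes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.groups)

    user_ids = [f"u{idx:04d}" for idx in range(spec.n_users)]
    group_idx = rng.choice(n_groups, size=spec.n_users, p=np.asarray(spec.cluster_mixture))
    age = rng.integers(20, 56, size=spec.n_users)
    sex = rng.choice(["F", "M"], size=spec.n_users, p=[0.52, 0.48])

    users = pd.DataFrame({"user_id": user_ids, "age": age, "sex": sex})

    pref = np.empty((spec.n_users, 3))
    offsets = rng.normal(0.0, 0.3, size=spec.n_users)
    night_rows: list[pd.DataFrame] = []
    resp_index: list[tuple[str, int]] = []
    resp_vals: list[np.ndarray] = []

    for u in range(spec.n_users):
        g = spec.groups[group_idx[u]]
        nn = spec.n_nights
        # Preference direction: group direction + user-specific jitter,
        # normalized so groups differ in direction, not magnitude — every
        # user then has both well- and poorly-matched catalog items.
        raw_pref = np.asarray(g.pref) + rng.normal(0.0, 0.15, size=3)
        pref[u] = 1.15 * raw_pref / np.linalg.norm(raw_pref)

        daily_rate = rng.lognormal(g.steps_log_mean, g.steps_log_sd, size=nn)
        steps = rng.poisson(daily_rate).astype(float)
        hr_mean = _truncnorm(rng, g.hr_mean, g.hr_mean_sd, 40, 120, nn)
        hr_sd = _truncnorm(rng, g.hr_sd_mean, 2.0, 1, 30, nn)
        stress = _truncnorm(rng, g.stress_mean, g.stress_sd, 0, 100, nn)
        fatigue = _truncnorm(
            rng, 0.6 * stress + 0.4 * g.fatigue_mean, g.fatigue_sd * 0.7, 0, 100, nn
        )

        # Environment is group-independent (nuisance for clustering).
        temperature = rng.normal(21.0, 1.5, size=nn)
        humidity = rng.normal(45.0, 6.0, size=nn)
        light = np.abs(rng.normal(8.0, 5.0, size=nn))    # lux at night
        noise = np.abs(rng.normal(32.0, 6.0, size=nn))   # dBA

        # Sleep outcomes: group baseline plus within-user coupling to the day.
        z_steps = (np.log(steps + 1) - g.steps_log_mean) / g.steps_log_sd
        z_stress = (stress - g.stress_mean) / g.stress_sd
        tst = _truncnorm(rng, g.tst_mean + 8 * z_steps - 8 * z_stress, g.tst_sd, 120, 680, nn)
        sol = np.maximum(1.0, rng.gamma(2.0, (8.0 + 0.15 * stress) / 2.0, size=nn))
        waso = np.maximum(0.0, rng.gamma(2.0, (6.0 + 0.2 * stress) / 2.0, size=nn))
        time_in_bed = tst + sol + waso
        efficiency = tst / time_in_bed

        bedtime = (1410 + rng.normal(0, 25, size=nn)) % 1440  # ~23:30

        # Bed-derived nightly features (what the signal pipeline would yield).
        resp_hz = _truncnorm(rng, 0.24, 0.035, 0.14, 0.42, nn)
        resp_rate = 60.0 * resp_hz
        posture_transitions = rng.poisson(6.0 + stress / 15.0).astype(float)
        micro_movement = rng.gamma(3.0, (0.8 + stress / 120.0) / 3.0, size=nn)
        pressure_entropy = _truncnorm(rng, 2.4, 0.35, 0.0, 4.0, nn)

        # Nightly subjective 1-5 rating of perceived sleep quality.
        quality = _truncnorm(
            rng, g.quality_mean + 0.25 * z_steps - 0.25 * z_stress, g.quality_sd, 0.5, 5.5, nn
        )
        rated = rng.random(nn) < spec.nightly_rating_rate
        rating = np.where(rated, np.clip(round_half_up(quality), 1, 5), np.nan)

        night_rows.append(pd.DataFrame({
            "user_id": user_ids[u],
            "night": np.arange(nn),
            "steps": steps, "hr_mean": hr_mean, "hr_sd": hr_sd,
            "stress": stress, "fatigue": fatigue,
            "temperature": temperature, "humidity": humidity,
            "light": light, "noise": noise,
            "bedtime_min": bedtime,
            "time_in_bed": time_in_bed, "tst": tst, "sol": sol, "waso": waso,
            "efficiency": efficiency,
            "resp_rate": resp_rate, "posture_transitions": posture_transitions,
            "micro_movement": micro_movement, "pressure_entropy": pressure_entropy,
            "location_category": rng.choice(
                ["home", "travel", "mixed"], size=nn, p=[0.9, 0.04, 0.06]
            ),
            "gap_minutes": 0.0,
            "rating": rating,
        }))
        resp_index.extend((user_ids[u], n) for n in range(nn))
        resp_vals.append(resp_hz)

    nights = pd.concat(night_rows, ignore_index=True)
    truth = LatentTruth(
        group=pd.Series(group_idx, index=user_ids, name="group"),
        pref_vectors=pd.DataFrame(pref, index=user_ids, columns=["p0", "p1", "p2"]),
        user_offset=pd.Series(offsets, index=user_ids, name="offset"),
        resp_rate_hz=pd.Series(
            np.concatenate(resp_vals),
            index=pd.MultiIndex.from_tuples(resp_index, names=["user_id", "night"]),
        ),
    )
    return Cohort(users=users, nights=nights), truth


def true_utilities(truth: LatentTruth, catalog) -> pd.DataFrame:
    """Low-rank true utility: 1.2 + 2.8 * (pref . item_attrs) + user offset.

    The affine map places a user's best-matched items around 4-4.5 and
    poorly matched ones below 2 on the 1-5 rating scale, so every user has
    both liked (>= 4) and disliked items — the preference signal the
    feedback re-ranking stage is meant to recover.
    """
    attrs = np.stack([np.asarray(item.attributes, dtype=float) for item in catalog.items])
    raw = 1.2 + 2.8 * (truth.pref_vectors.to_numpy() @ attrs.T)
    raw = raw + truth.user_offset.to_numpy()[:, None]
    return pd.DataFrame(raw, index=truth.pref_vectors.index,
                        columns=[item.item_id for item in catalog.items])


def generate_ratings(
    cohort: Cohort,
    truth: LatentTruth,
    catalog,
    noise_sd: float | None = None,
    rated_fraction: float = 0.8,
    reps_range: tuple[int, int] = (2, 6),
    seed: int = 1,
) -> pd.DataFrame:
    """Long table of per-night 1-5 item ratings.

    Each user rates a seeded subset of catalog items; a rated (user, item)
    pair accumulates several night-level ratings, each
    ``clip(round(utility + N(0, noise_sd)), 1, 5)`` with half-up rounding.
    """
    if len(catalog.items) == 0:
        raise ValueError("catalog must be non-empty")
    if noise_sd is None:
        noise_sd = 0.5
    rng = np.random.default_rng(seed)
    util = true_utilities(truth, catalog)
    truth.utilities = util

    n_nights = int(cohort.nights["night"].max()) + 1
    rows: list[tuple[str, str, int, float]] = []
    for user_id in util.index:
        for item_id in util.columns:
            if rng.random() >= rated_fraction:
                continue
            n_reps = int(rng.integers(reps_range[0], reps_range[1] + 1))
            nights = rng.choice(n_nights, size=min(n_reps, n_nights), replace=False)
            vals = util.loc[user_id, item_id] + rng.normal(0.0, noise_sd, size=len(nights))
            for night, v in zip(nights, vals):
                rows.append((user_id, item_id, int(night),
                             float(np.clip(round_half_up(v), 1, 5))))
    return pd.DataFrame(rows, columns=["user_id", "item_id", "night", "rating"])


def rating_matrix(ratings_long: pd.DataFrame) -> pd.DataFrame:
    """users x items matrix; multiple night ratings aggregated by mean."""
    return ratings_long.pivot_table(
        index="user_id", columns="item_id", values="rating", aggfunc="mean"
    )


def inject_missingness(
    cohort: Cohort,
    missing: MissingnessSpec,
    truth: LatentTruth | None = None,
    seed: int = 2,
) -> Cohort:
    """Blank values per the three mechanisms; log each injection into truth.

    Short gaps are strictly < 30 min and blank one wearable channel for one
    night (the length is recorded in the observable ``gap_minutes`` column,
    as a recording device would log it).  Whole-night drops blank either the
    full wearable or the full bed block.  Unknown-category injections blank
    ``location_category``.
    """
    missing.validate()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    nights = out.nights
    n = len(nights)
    log: list[dict] = []

    gap_mask = rng.random(n) < missing.gap_rate
    for i in np.flatnonzero(gap_mask):
        channel = str(rng.choice(WEARABLE_CHANNELS))
        minutes = float(rng.uniform(5.0, 29.9))  # strictly < 30
        nights.loc[i, channel] = np.nan
        nights.loc[i, "gap_minutes"] = minutes
        log.append({"kind": "gap", "row": int(i), "channel": channel, "minutes": minutes})

    drop_mask = (rng.random(n) < missing.drop_rate) & ~gap_mask
    for i in np.flatnonzero(drop_mask):
        block = WEARABLE_CHANNELS if rng.random() < 0.5 else BED_CHANNELS
        nights.loc[i, block] = np.nan
        log.append({"kind": "night_drop", "row": int(i),
                    "channel": "wearable" if block is WEARABLE_CHANNELS else "bed",
                    "minutes": np.nan})

    unk_mask = rng.random(n) < missing.unknown_rate
    nights.loc[unk_mask, "location_category"] = np.nan
    log.extend({"kind": "unknown", "row": int(i), "channel": "location_category",
                "minutes": np.nan} for i in np.flatnonzero(unk_mask))

    if truth is not None:
        truth.injections = pd.DataFrame(
            log, columns=["kind", "row", "channel", "minutes"]
        )
    return out


def generate_cohort(spec: CohortSpec, catalog=None) -> tuple[Cohort, LatentTruth]:
    """Population + item ratings + injected missingness in one seeded call."""
    if catalog is None:
        from .recommend import default_catalog
        catalog = default_catalog()
    cohort, truth = generate_population(spec)
    cohort.ratings = generate_ratings(
        cohort, truth, catalog,
        noise_sd=spec.rating_noise_sd,
        rated_fraction=spec.rated_fraction,
        seed=spec.seed + 1,
    )
    cohort = inject_missingness(cohort, spec.missingness, truth, seed=spec.seed + 2)
    return cohort, truth


def save_cohort(cohort: Cohort, truth: LatentTruth | None, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.users.to_csv(out / "users.csv", index=False)
    cohort.nights.to_csv(out / "nights.csv", index=False)
    if cohort.ratings is not None:
        cohort.ratings.to_csv(out / "ratings.csv", index=False)
    if truth is not None:
        truth.to_json(out / "truth.json")


def load_cohort(in_dir: str | Path) -> Cohort:
    p = Path(in_dir)
    ratings = p / "ratings.csv"
    return Cohort(
        users=pd.read_csv(p / "users.csv"),
        nights=pd.read_csv(p / "nights.csv"),
        ratings=pd.read_csv(ratings) if ratings.exists() else None,
    )


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (e.g. parsed YAML)."""
    kwargs = dict(d)
    if "missingness" in kwargs and isinstance(kwargs["missingness"], dict):
        kwargs["missingness"] = MissingnessSpec(**kwargs["missingness"])
    if "cluster_mixture" in kwargs:
        kwargs["cluster_mixture"] = tuple(kwargs["cluster_mixture"])
    if "groups" in kwargs:
        kwargs["groups"] = tuple(
            g if isinstance(g, GroupParams) else GroupParams(**g) for g in kwargs["groups"]
        )
    valid = {f.name for f in dataclasses.fields(CohortSpec)}
    return CohortSpec(**{k: v for k, v in kwargs.items() if k in valid})
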