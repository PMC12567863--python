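# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Synthetic cohort

The generator emulates a 12-week wearable + smart-bed study of ~100
community-dwelling adults. Users are drawn from three latent lifestyle
groups with mixture (0.20, 0.10, 0.70), mirroring the retained-user
proportions such studies report when profiling clusters:

| group | stress | activity | latent quality (1–5) |
|---|---|---|---|
| 0 | moderate (55 ± 9) | irregular (step log-SD 0.55) | 3.9 |
| 1 | high (76 ± 8) | low (~3.5 k steps/day) | 2.8 |
| 2 | low (30 ± 8) | high (~12.5 k steps/day) | 4.4 |

Design choices, each made once:

* **Steps** are Poisson-lognormal — a lognormal daily activity rate followed
  by a Poisson draw — the simplest family for positive, overdispersed counts
  whose log-SD directly encodes "irregular activity".
* **Continuous physiology** (HR, stress, fatigue) is Gaussian truncated at
  physical bounds by resampling. Fatigue is coupled to stress
  (0.6·stress + 0.4·group mean) because both derive from the same HRV
  source in real devices.
* **Sleep outcomes** couple to the day within user: TST rises with the
  night's activity z-score and falls with its stress z-score, on top of the
  group baseline; SOL and WASO are Gamma with stress-dependent scale;
  efficiency = TST / time-in-bed by construction.
* **Item preferences** are low-rank: each user has a 3-d preference
  direction (group direction + jitter, normalized to a common magnitude of
  1.15) over item attributes (schedule-regularity, activity,
  stress/environment relief). Utilities are `1.2 + 2.8·(pref·attrs) +
  user offset`, placing each user's best-matched items near 4–4.5 and
  poorly matched ones below 2 — so "liked" (≥4) and "disliked" items both
  exist for every user, the signal the feedback re-ranker is meant to
  recover. Normalizing preference *magnitude* (groups differ only in
  direction) is deliberate: without it, a group whose direction is spread
  across several attributes would never reach the liked range.
* **Ratings** are `clip(round(utility + N(0, 0.5)), 1, 5)` with half-up
  rounding (so 2.5 → 3 deterministically); a (user, item) pair accumulates
  2–6 night-level ratings that are aggregated by mean before matrix
  construction. Nightly 1–5 perceived-quality ratings are generated
  separately from the latent quality with the same discretization.
* **Missingness** has three mechanisms with defaults gap 2 %,
  whole-night drop 0.9 % (reproducing the ~72-of-8400 removal scale),
  unknown-category 1 %. A "gap" blanks one wearable channel of one night
  and records its (strictly <30 min) length in an observable
  `gap_minutes` column, the way a recording device logs its own outages;
  gaps operate at nightly-aggregate granularity rather than on raw minute
  streams — the same imputation rules, one level coarser.

Ground truth (group labels, preference vectors, utilities, per-night
respiration rates, injection log) lives in `LatentTruth`, which the
pipeline never reads; only recovery tests do.

What the generator does **not** emulate: proprietary HRV algorithms (stress
and fatigue are declared proxies), weekday/weekend structure, seasonal
drift, device-specific noise signatures, attrition, or any correlation
between rating behaviour and compliance. Passing tests therefore show the
pipeline recovers the structure it assumes, not that real cohorts contain
that structure.

## Bed-signal pipeline

`simulate_night` plants a respiration sinusoid (0.1–0.5 Hz), a cardiac
sinusoid (default 1.2 Hz), white noise, and large spike artifacts in the
50 Hz load channel; the pressure grid concentrates weight on
posture-dependent cells; the observed posture sequence is the scheduled
truth with symmetric flips.

Preprocessing choices:

* **Hampel**: half-window 5 samples, threshold 3 scaled MADs (factor
  1.4826), edge windows truncated. The filter is not strictly idempotent on
  arbitrary noise (replacement shrinks local MADs), but is idempotent in
  its design regime — smooth signal plus isolated spikes — which is what
  the suite asserts.
* **Band-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`) for zero phase. Filtering happens at 50 Hz *before*
  decimation; because the respiration band lies below 0.5 Hz, averaging
  into 1 s bins attenuates but cannot alias it.
* **Resampling**: mean within each 1 s bin; a stream whose length is not a
  whole number of seconds is rejected by name. Clock synchronization is
  simulated by construction (shared timestamps).
* **Posture smoothing**: 4-state sticky HMM (self-transition 0.95,
  symmetric emission error 0.1), Viterbi-decoded via hmmlearn with fixed
  parameters. Tests verify the decode against exhaustive path enumeration
  at T = 8 — on log-probability, since the symmetric parameters make
  distinct maximizing paths common.
* **Features**: respiratory rate = 60 × the dominant Welch frequency (60 s
  segments, 50 % overlap) of the respiration-band channel, giving 1
  breath/min resolution (≤0.5 bpm worst-case bin error) at night lengths of
  a few minutes and above; micro-movement index = mean |Δ| of total grid
  pressure at 1 Hz (any cohort-level scaling is a profiling concern);
  pressure entropy = Shannon entropy (bits) of the night-averaged
  normalized spatial distribution, bounded by log2(#cells). The last two
  formulas are declared conventions — the feature *names* are standard, the
  definitions are this package's.

## Profiling and the 68-feature schema

The schema (version 1) is fixed and enumerable: 32 lagged-history
components ({3,7}-night trailing mean/SD of 8 signals, previous nights
only), 12 current-night components (incl. prior-night rating, which falls
back to the user mean then the cohort mean), 8 bed components, 4
environment means, sleep debt, 4 circadian components (sin/cos of bedtime
and midsleep; already unit-scale, left un-z-scored), age, sex one-hot (2),
activity one-hot (4). Continuous components are z-scored on training-user
statistics only; the builder stores those statistics plus the step-quartile
cuts so unseen users are encoded without leakage. First-night lag windows
fall back to the current value (mean) and 0 (SD) to keep vectors finite.

Per-user quality scores z-score nightly ratings against the *cohort* grand
mean/SD and average within user. (A strictly per-user z-score would make
every user's mean identically zero — normalizing across the cohort keeps
the normalize-then-aggregate intent while preserving a usable cross-user
ordering.)

Activity categories: low/high = bottom/top quartile of mean daily steps,
irregular = day-to-day CV above the 75th percentile (taking precedence),
else typical. Because the CV rule is a relative quantile, some user is
always "irregular" in any cohort — it describes the tail, not an absolute
variability level.

## Cluster refinement

Three stages, all seeded: (1) feature screen — of each |r| ≥ 0.90 pair drop
the member with the lower ANOVA F against provisional labels (k = 3 K-means
on all standardized features, seed 42); drop features whose F is not
significant at p ≤ 0.05; drop the bottom decile of surviving F scores
(skipped if fewer than two features would remain); (2) PCA keeping the
smallest m with cumulative explained variance ≥ 0.85; (3) K-means
(k-means++, n_init 50, max_iter 500, tol 1e-4, random_state 42) for
k ∈ [2, 6], keeping the silhouette argmax with ties to the smaller k.
Silhouette is computed in the PCA space — the space actually clustered.

The significance screen exists because a decile rule alone cannot remove
several simultaneously uninformative features: in cohorts with multiple
flat environment aggregates the noise dimensions survive into PCA, dilute
the silhouette below the raw-feature baseline, and k = 2 wins. Requiring
cluster-signal significance removes exactly the variables that carry
variance but no separation.

Users with per-sample silhouette < 0.1 are flagged ambiguous: they keep a
label for recommendation fallback but are excluded from cluster profiling
(`labels_series()` reports them as −1).

## Recommenders

CBSUR searches the target's cluster for users with a strictly higher
quality score and returns the cosine-similarity argmax of profile feature
vectors (ties broken by user id; zero vectors get similarity 0 with a
warning rather than an error — a degenerate profile should not crash
recommendation).

PFRA neighbourhoods are restricted to the user's cluster, falling back to
the global pool when the cluster has fewer than K other members or the user
is unclustered; negative similarities are excluded so the prediction is a
convex combination of neighbour ratings (bounded by their min/max and
shift-equivariant). When no positive-similarity neighbour rated the item,
the item mean is returned with a flag. Defaults K_neighbors = 10,
K_items = 5. Ranking ties break by ascending item id for determinism.

## MLP ranker

Implemented in plain numpy (no NN framework dependency): two 128-unit
hidden layers (ReLU, batch normalization, inverted dropout 0.2) into a
64-unit shared representation; the relevance head scores
[shared ⊕ 8-d item embedding] through one 32-unit ReLU layer — a purely
linear head on a concatenation is additive in user and item and cannot
rank items differently for different users, so one hidden layer is the
minimal interaction-capable head; the fatigue head is linear on the shared
representation. Losses: BPR `−mean log σ(s⁺ − s⁻)` (computed in
log-sigmoid stable form) + λ·Huber (λ = 0.1, δ = 1 rating unit) on the
z-scored next-day fatigue index. Optimizer: AdamW with decoupled weight
decay on weight matrices and embeddings only (lr 3e-4, wd 1e-2 defaults);
batches of 256, ≤100 epochs, early stopping with patience 10 on the
validation combined loss, best weights restored. Batch-norm running
statistics (momentum 0.1) drive evaluation mode, so inference is
deterministic. Every gradient is hand-derived and checked against central
finite differences; the check perturbs parameters off zero first, because
zero-initialized biases put some ReLU pre-activations exactly at their
kink, where finite differences measure the average of the two one-sided
slopes rather than the subgradient backprop uses.

Pair construction: positives are items rated ≥ 4 by the user, negatives
are sampled from items rated ≤ 2 or unrated; up to 6 nights per user per
epoch-independent draw. Fusion with PFRA: per-user min-max normalization
of each score vector (a constant vector becomes 0.5 with a warning), then
`α·pfra + (1−α)·mlp` with α = 0.5 by default.

## Evaluation protocol

Relevance: aggregated rating ≥ 4 (configurable). Splits are grouped by
user (70/10/20, seeded, exact to rounding); nights remain chronological
because splitting never reorders them. Since test users contribute no
training ratings, each test user's rated items are split half observed /
half held out (seeded): observed ratings condition the CF/CBF baselines,
and mAP/F1 are measured on the ranking of non-observed items at top-5.
Users with no relevant held-out item are excluded from averaging (AP with
zero relevant items is defined as 0 and flagged). Baselines: CF = the
neighbourhood predictor without cluster restriction, with similarity from
mean-centred rating vectors; CBF = cosine between item attributes and the
centroid of the user's observed liked items; hybrid = equal-weight fusion
of the two. The grid reports mean ± SD over three seeds.

Problem sizes in the shipped experiment configuration (60 users × 28
nights, 10-item catalog, 20-epoch training) are chosen so a full
three-seed grid completes in seconds while every stage still has a
recoverable planted signal; the 300-user × 56-night cohort used for
cluster recovery matches the regime where the silhouette criterion is
stable.

## Known limitations

* The 10-item catalog makes top-5 F1 weakly discriminative (top-5 covers
  most of the candidate set); mAP is the informative metric at this scale.
* The MLP sees only 68 user-night features plus an item embedding; with
  small synthetic cohorts it is usually the weakest ranker, which is
  exactly why the fused and re-ranked variants dominate in the ablation.
* Absolute mAP/F1 on synthetic cohorts are not comparable to numbers
  reported on any real cohort; only directions and orderings transfer.
* The REST-style input swap is supported only as a feature-table hook:
  any per-night stage-fraction table can be merged into the nights table
  before feature building; no stage classifier is re-implemented.
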