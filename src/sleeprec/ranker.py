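"""Hybrid MLP ranker: early-fusion network with BPR + Huber training.

The relevance model scores (user-night, item) pairs.  A shared trunk maps
the 68-component user-night feature vector through two 128-unit hidden
layers (ReLU, batch normalization, dropout 0.2) into a 64-unit shared
representation; a relevance head scores the concatenation of that
representation with a learned 8-dimensional item embedding, and an
auxiliary head regresses next-day fatigue.  Training minimizes

    L = L_BPR + lambda * L_Huber,    lambda = 0.1 by default,

where L_BPR = -mean log sigmoid(s+ - s-) over (positive, negative) item
pairs and L_Huber is the fatigue regression loss (delta = 1).  The
optimizer is AdamW (decoupled weight decay; lr 3e-4, wd 1e-2), batch size
256, at most 100 epochs with early stopping on the validation combined
loss.  Everything is plain numpy with hand-derived gradients; a finite-
difference test in the suite guards the backward pass.

Final rankings can fuse the network's scores with the feedback re-ranking
(PFRA) scores: both are min-max normalized per user and mixed with weight
alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "bpr_loss",
    "huber_loss",
    "combined_loss",
    "fuse_scores",
    "RankerNet",
    "TrainConfig",
    "MLPRanker",
]

_EPS = 1e-5  # batch-norm variance floor


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    # stable: log sigma(z) = -log(1 + exp(-z)) = min(z,0) - log1p(exp(-|z|))
    return np.minimum(z, 0.0) - np.log1p(np.exp(-np.abs(z)))


def bpr_loss(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Bayesian Personalized Ranking loss: -mean log sigma(s+ - s-)."""
    pos = np.asarray(pos_scores, dtype=float).ravel()
    neg = np.asarray(neg_scores, dtype=float).ravel()
    if pos.size == 0 or pos.shape != neg.shape:
        raise ValueError("pos/neg score vectors must be non-empty and equal length")
    return float(-np.mean(_log_sigmoid(pos - neg)))


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> float:
    """Mean Huber loss: quadratic within +-delta, linear beyond."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    r = np.asarray(pred, dtype=float) - np.asarray(target, dtype=float)
    a = np.abs(r)
    per = np.where(a <= delta, 0.5 * r ** 2, delta * (a - 0.5 * delta))
    return float(np.mean(per))


def combined_loss(bpr: float, huber: float, lam: float = 0.1) -> float:
    """L = L_BPR + lambda * L_Huber."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(bpr + lam * huber)


def fuse_scores(mlp_scores: np.ndarray, pfra_scores: np.ndarray,
                alpha: float = 0.5) -> np.ndarray:
    """Per-user score fusion: min-max normalize each, mix with weight alpha.

    ``alpha`` is the weight on the PFRA (feedback) scores; 0 reproduces the
    MLP ranking, 1 the PFRA ranking.  A constant score vector normalizes to
    0.5 everywhere (with a warning) so it cannot dominate either way.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    m = np.asarray(mlp_scores, dtype=float)
    p = np.asarray(pfra_scores, dtype=float)
    if m.shape != p.shape:
        raise ValueError("score vectors must cover the same items")

    def _norm(s: np.ndarray) -> np.ndarray:
        lo, hi = s.min(), s.max()
        if hi - lo == 0:
            warnings.warn("constant score vector normalized to 0.5")
            return np.full_like(s, 0.5)
        return (s - lo) / (hi - lo)

    return alpha * _norm(p) + (1 - alpha) * _norm(m)


# ---------------------------------------------------------------------------
# Network


class RankerNet:
    """Parameter container + forward/backward for the two-head network."""

    def __init__(self, n_items: int, n_features: int = 68,
                 hidden: tuple[int, int] = (128, 128), shared_dim: int = 64,
                 embed_dim: int = 8, head_dim: int = 32, dropout: float = 0.2,
                 seed: int = 0):
        self.n_items = n_items
        self.n_features = n_features
        self.hidden = hidden
        self.shared_dim = shared_dim
        self.embed_dim = embed_dim
        self.head_dim = head_dim
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        h1, h2 = hidden

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params: dict[str, np.ndarray] = {
            "W1": he(n_features, (n_features, h1)), "b1": np.zeros(h1),
            "g1": np.ones(h1), "be1": np.zeros(h1),
            "W2": he(h1, (h1, h2)), "b2": np.zeros(h2),
            "g2": np.ones(h2), "be2": np.zeros(h2),
            "W3": he(h2, (h2, shared_dim)), "b3": np.zeros(shared_dim),
            "E": rng.normal(0.0, 0.1, size=(n_items, embed_dim)),
            # relevance head: one hidden ReLU layer over [h ++ e] so the
            # score can express user-item interactions (a purely linear
            # head on a concatenation is additive and cannot)
            "Wr1": he(shared_dim + embed_dim, (shared_dim + embed_dim, head_dim)),
            "br1": np.zeros(head_dim),
            "Wr2": he(head_dim, (head_dim, 1)), "br2": np.zeros(1),
            "Wf": he(shared_dim, (shared_dim, 1)), "bf": np.zeros(1),
        }
        # batch-norm running statistics (not trained by gradient)
        self.run_mean = {"1": np.zeros(h1), "2": np.zeros(h2)}
        self.run_var = {"1": np.ones(h1), "2": np.ones(h2)}
        self.bn_momentum = 0.1

    # -- forward pieces -----------------------------------------------------

    def _bn_forward(self, z, layer: str, train: bool):
        g = self.params[f"g{layer}"]
        be = self.params[f"be{layer}"]
        if train:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.run_mean[layer] = (1 - self.bn_momentum) * self.run_mean[layer] \
                + self.bn_momentum * mu
            self.run_var[layer] = (1 - self.bn_momentum) * self.run_var[layer] \
                + self.bn_momentum * var
        else:
            mu, var = self.run_mean[layer], self.run_var[layer]
        inv_sd = 1.0 / np.sqrt(var + _EPS)
        xhat = (z - mu) * inv_sd
        return g * xhat + be, (xhat, inv_sd, g)

    @staticmethod
    def _bn_backward(dy, cache, train: bool):
        xhat, inv_sd, g = cache
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        if train:
            n = dy.shape[0]
            dx = (g * inv_sd / n) * (
                n * dy - dbeta - xhat * (dy * xhat).sum(axis=0)
            )
        else:
            dx = dy * g * inv_sd
        return dx, dgamma, dbeta

    def forward_shared(self, X, train: bool, masks=None, rng=None):
        """Trunk forward; returns the shared representation and caches."""
        p = self.params
        cache: dict = {"X": X}
        z1 = X @ p["W1"] + p["b1"]
        bn1, cache["bn1"] = self._bn_forward(z1, "1", train)
        a1 = np.maximum(bn1, 0.0)
        cache["relu1"] = bn1 > 0
        if train and self.dropout > 0:
            m1 = masks[0] if masks is not None else (
                rng.random(a1.shape) >= self.dropout) / (1 - self.dropout)
            a1 = a1 * m1
            cache["m1"] = m1
        z2 = a1 @ p["W2"] + p["b2"]
        cache["a1"] = a1
        bn2, cache["bn2"] = self._bn_forward(z2, "2", train)
        a2 = np.maximum(bn2, 0.0)
        cache["relu2"] = bn2 > 0
        if train and self.dropout > 0:
            m2 = masks[1] if masks is not None else (
                rng.random(a2.shape) >= self.dropout) / (1 - self.dropout)
            a2 = a2 * m2
            cache["m2"] = m2
        cache["a2"] = a2
        z3 = a2 @ p["W3"] + p["b3"]
        h = np.maximum(z3, 0.0)
        cache["relu3"] = z3 > 0
        cache["h"] = h
        return h, cache

    def _backward_shared(self, dh, cache, train: bool, grads):
        p = self.params
        dz3 = dh * cache["relu3"]
        grads["W3"] += cache["a2"].T @ dz3
        grads["b3"] += dz3.sum(axis=0)
        da2 = dz3 @ p["W3"].T
        if train and self.dropout > 0:
            da2 = da2 * cache["m2"]
        dbn2 = da2 * cache["relu2"]
        dz2, dg2, dbe2 = self._bn_backward(dbn2, cache["bn2"], train)
        grads["g2"] += dg2
        grads["be2"] += dbe2
        grads["W2"] += cache["a1"].T @ dz2
        grads["b2"] += dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        if train and self.dropout > 0:
            da1 = da1 * cache["m1"]
        dbn1 = da1 * cache["relu1"]
        dz1, dg1, dbe1 = self._bn_backward(dbn1, cache["bn1"], train)
        grads["g1"] += dg1
        grads["be1"] += dbe1
        grads["W1"] += cache["X"].T @ dz1
        grads["b1"] += dz1.sum(axis=0)

    def relevance(self, h, item_idx):
        """Score each row of h against its item: head(h ++ E[item])."""
        p = self.params
        e = p["E"][item_idx]
        he_cat = np.concatenate([h, e], axis=1)
        z = he_cat @ p["Wr1"] + p["br1"]
        a = np.maximum(z, 0.0)
        s = (a @ p["Wr2"] + p["br2"]).ravel()
        return s, (he_cat, z > 0, a)

    def _relevance_backward(self, ds, cache, grads):
        """Backprop a (n, 1) score gradient; returns d(concat input)."""
        p = self.params
        he_cat, relu, a = cache
        grads["Wr2"] += a.T @ ds
        grads["br2"] += ds.sum(axis=0)
        dz = (ds @ p["Wr2"].T) * relu
        grads["Wr1"] += he_cat.T @ dz
        grads["br1"] += dz.sum(axis=0)
        return dz @ p["Wr1"].T

    def score(self, X: np.ndarray, item_idx: np.ndarray) -> np.ndarray:
        """Evaluation-mode relevance scores (deterministic)."""
        h, _ = self.forward_shared(np.asarray(X, float), train=False)
        s, _ = self.relevance(h, np.asarray(item_idx, int))
        return s

    def predict_fatigue(self, X: np.ndarray) -> np.ndarray:
        p = self.params
        h, _ = self.forward_shared(np.asarray(X, float), train=False)
        return (h @ p["Wf"] + p["bf"]).ravel()

    # -- loss & gradients ---------------------------------------------------

    def loss_and_grads(self, X, pos_idx, neg_idx, fatigue_target,
                       lam: float = 0.1, delta: float = 1.0,
                       train: bool = True, masks=None, rng=None):
        """Combined BPR + lambda*Huber loss and gradients for one batch.

        When ``train`` is True, batch statistics and (fixed or seeded)
        dropout masks are used; passing explicit ``masks`` makes the
        forward pass a deterministic function of the parameters, which the
        finite-difference gradient test relies on.
        """
        p = self.params
        X = np.asarray(X, dtype=float)
        pos_idx = np.asarray(pos_idx, dtype=int)
        neg_idx = np.asarray(neg_idx, dtype=int)
        n = X.shape[0]

        h, cache = self.forward_shared(X, train, masks=masks, rng=rng)
        s_pos, head_pos = self.relevance(h, pos_idx)
        s_neg, head_neg = self.relevance(h, neg_idx)
        f_pred = (h @ p["Wf"] + p["bf"]).ravel()

        margin = s_pos - s_neg
        l_bpr = float(-np.mean(_log_sigmoid(margin)))
        l_hub = huber_loss(f_pred, fatigue_target, delta)
        loss = combined_loss(l_bpr, l_hub, lam)

        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # BPR head: dL/ds_pos = -sigma(-margin)/n, dL/ds_neg = +sigma(-margin)/n
        sig = 1.0 / (1.0 + np.exp(margin))
        ds_pos = (-sig / n)[:, None]
        ds_neg = (sig / n)[:, None]
        d = self.shared_dim
        dcat_pos = self._relevance_backward(ds_pos, head_pos, grads)
        dcat_neg = self._relevance_backward(ds_neg, head_neg, grads)
        dh = dcat_pos[:, :d] + dcat_neg[:, :d]
        np.add.at(grads["E"], pos_idx, dcat_pos[:, d:])
        np.add.at(grads["E"], neg_idx, dcat_neg[:, d:])

        # Huber head
        r = f_pred - np.asarray(fatigue_target, dtype=float)
        dhub = np.clip(r, -delta, delta) / n  # d(mean Huber)/d pred
        df = (lam * dhub)[:, None]
        grads["Wf"] += h.T @ df
        grads["bf"] += df.sum(axis=0)
        dh = dh + df @ p["Wf"].T

        self._backward_shared(dh, cache, train, grads)
        return loss, grads, {"bpr": l_bpr, "huber": l_hub}


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    lr: float = 3e-4
    weight_decay: float = 1e-2
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    lam: float = 0.1
    huber_delta: float = 1.0
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


class _AdamW:
    """Adam with decoupled weight decay on weight matrices and embeddings."""

    DECAYED_PREFIXES = ("W", "E")

    def __init__(self, params: dict[str, np.ndarray], lr: float, wd: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, wd
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            update = (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            if k.startswith(self.DECAYED_PREFIXES):
                update = update + self.wd * params[k]
            params[k] -= self.lr * update


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_bpr: list[float] = field(default_factory=list)
    best_epoch: int = -1


class MLPRanker(BaseEstimator):
    """sklearn-style wrapper around :class:`RankerNet` training.

    ``fit`` consumes aligned arrays: ``X`` (n, 68) user-night features,
    ``pairs`` (n, 2) integer (positive item, negative item) indices, and
    ``fatigue`` (n,) auxiliary regression targets.  Validation arrays
    drive early stopping; without them the full budget is used.  A fixed
    ``seed`` makes the run bit-reproducible.
    """

    def __init__(self, n_items: int, n_features: int = 68,
                 hidden: tuple[int, int] = (128, 128), shared_dim: int = 64,
                 embed_dim: int = 8, head_dim: int = 32, dropout: float = 0.2,
                 config: TrainConfig | None = None, seed: int = 0):
        self.n_items = n_items
        self.n_features = n_features
        self.hidden = hidden
        self.shared_dim = shared_dim
        self.embed_dim = embed_dim
        self.head_dim = head_dim
        self.dropout = dropout
        self.config = config
        self.seed = seed

    def fit(self, X, pairs, fatigue, X_val=None, pairs_val=None, fatigue_val=None):
        cfg = self.config or TrainConfig()
        rng = np.random.default_rng(self.seed)
        net = RankerNet(self.n_items, self.n_features, self.hidden,
                        self.shared_dim, self.embed_dim, self.head_dim,
                        self.dropout, seed=self.seed)
        opt = _AdamW(net.params, cfg.lr, cfg.weight_decay)
        X = np.asarray(X, dtype=float)
        pairs = np.asarray(pairs, dtype=int)
        fatigue = np.asarray(fatigue, dtype=float)
        n = X.shape[0]
        history = TrainHistory()
        best_val = np.inf
        best_params = None
        best_run = None
        bad_epochs = 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if idx.size < 2:
                    continue  # batch norm needs >= 2 samples
                loss, grads, _ = net.loss_and_grads(
                    X[idx], pairs[idx, 0], pairs[idx, 1], fatigue[idx],
                    lam=cfg.lam, delta=cfg.huber_delta, train=True, rng=rng,
                )
                opt.step(net.params, grads)
                epoch_loss += loss * idx.size
            history.train_loss.append(epoch_loss / n)

            if X_val is not None:
                vl, vb = self._eval_loss(net, X_val, pairs_val, fatigue_val, cfg)
                history.val_loss.append(vl)
                history.val_bpr.append(vb)
                if vl < best_val - 1e-6:
                    best_val = vl
                    best_params = {k: v.copy() for k, v in net.params.items()}
                    best_run = ({k: v.copy() for k, v in net.run_mean.items()},
                                {k: v.copy() for k, v in net.run_var.items()})
                    history.best_epoch = epoch
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > cfg.patience:
                        break

        if best_params is not None:
            net.params = best_params
            net.run_mean, net.run_var = best_run
        self.net_ = net
        self.history_ = history
        return self

    @staticmethod
    def _eval_loss(net, X, pairs, fatigue, cfg):
        X = np.asarray(X, dtype=float)
        pairs = np.asarray(pairs, dtype=int)
        s_pos = net.score(X, pairs[:, 0])
        s_neg = net.score(X, pairs[:, 1])
        lb = bpr_loss(s_pos, s_neg)
        lh = huber_loss(net.predict_fatigue(X), np.asarray(fatigue, float),
                        cfg.huber_delta)
        return combined_loss(lb, lh, cfg.lam), lb

    def score_items(self, x: np.ndarray, item_idx=None) -> np.ndarray:
        """Relevance scores of one user-night vector against items."""
        if item_idx is None:
            item_idx = np.arange(self.n_items)
        item_idx = np.asarray(item_idx, dtype=int)
        Xrep = np.tile(np.asarray(x, float).reshape(1, -1), (item_idx.size, 1))
        return self.net_.score(Xrep, item_idx)

    def predict_fatigue(self, X) -> np.ndarray:
        return self.net_.predict_fatigue(np.asarray(X, float))
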