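"""Classifiers and feature selectors.

* :func:`train_graphsage` — a two-layer (configurable 0–4) mean-aggregator
  GraphSAGE for transductive node classification on the population graph,
  implemented directly in numpy (forward pass, manual backprop, Adam) so the
  whole pipeline is deterministic under a single seed.
* :func:`train_baseline` — the five classical baselines (LR, LDA, kNN,
  Gaussian NB, RBF-SVM) as scikit-learn estimators.
* :func:`select_features` — filter/wrapper feature selection: CFS, CMIM,
  DISR, ICAP, Laplacian score, SVM-backward elimination, or none.

Mutual information for the information-theoretic filters is estimated on
quantile-binned features (5 bins by default), which is deterministic and
adequate at cohort sizes of a few hundred samples.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .graph import PopulationGraph

__all__ = [
    "SageConfig",
    "SageModel",
    "train_graphsage",
    "train_baseline",
    "select_features",
    "SELECTOR_METHODS",
    "BASELINE_NAMES",
]

SELECTOR_METHODS = ("CFS", "CMIM", "DISR", "ICAP", "LAP", "SVMB", "all")
BASELINE_NAMES = ("LR", "LDA", "KNN", "NB", "SVM")


# ---------------------------------------------------------------------------
# Mutual-information machinery (quantile binning)
# ---------------------------------------------------------------------------

def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(edges), x, side="right").astype(np.int64)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.max() + 1, b.max() + 1
    return np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    c = _joint_counts(a, b)
    return (
        _entropy_from_counts(c.sum(axis=1))
        + _entropy_from_counts(c.sum(axis=0))
        - _entropy_from_counts(c.ravel())
    )


def _cond_mi(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """I(a; b | c) for discrete arrays."""
    total = len(c)
    out = 0.0
    for val in np.unique(c):
        m = c == val
        out += m.sum() / total * _mi(a[m], b[m])
    return out


def _pack(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a * (b.max() + 1) + b


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def _cfs(X: np.ndarray, y: np.ndarray, max_stale: int = 5) -> np.ndarray:
    """Correlation-based feature selection by best-first forward search.

    Subset merit = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with Pearson correlations
    (absolute values) between features and the class / among features.
    The search stops after ``max_stale`` consecutive non-improving
    expansions, returning features in order of addition.
    """
    d = X.shape[1]
    with np.errstate(invalid="ignore"):
        r_cf = np.abs(np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(d)]))
        r_ff = np.abs(np.corrcoef(X, rowvar=False))
    r_cf = np.nan_to_num(r_cf)
    r_ff = np.nan_to_num(r_ff)

    def merit(subset: tuple) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        rcf = r_cf[list(subset)].mean()
        if k == 1:
            return rcf
        idx = np.array(subset)
        rff = (r_ff[np.ix_(idx, idx)].sum() - k) / (k * (k - 1))
        return k * rcf / np.sqrt(k + k * (k - 1) * rff)

    heap = [(-0.0, ())]
    best_merit, best_set = 0.0, ()
    visited = {()}
    stale = 0
    while heap and stale < max_stale:
        neg, subset = heapq.heappop(heap)
        improved = False
        for j in range(d):
            if j in subset:
                continue
            cand = subset + (j,)
            key = tuple(sorted(cand))
            if key in visited:
                continue
            visited.add(key)
            m = merit(cand)
            heapq.heappush(heap, (-m, cand))
            if m > best_merit + 1e-12:
                best_merit, best_set = m, cand
                improved = True
        stale = 0 if improved else stale + 1
    return np.array(best_set, dtype=int)


def _greedy_info(X_bin, y, k, score_fn, first_fn):
    d = X_bin.shape[1]
    relevance = np.array([_mi(X_bin[:, j], y) for j in range(d)])
    selected = [int(np.argmax(first_fn(relevance)))]
    while len(selected) < k:
        best_j, best_s = -1, -np.inf
        for j in range(d):
            if j in selected:
                continue
            s = score_fn(j, selected, relevance)
            if s > best_s:
                best_j, best_s = j, s
        selected.append(best_j)
    return np.array(selected, dtype=int)


def select_features(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    n_bins: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Select feature indices on (standardized) training data.

    Returns indices ordered by selection rank.  ``CFS`` ignores ``k`` (its
    best-first search sizes the subset itself) and ``all`` returns the
    identity ordering.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(np.int64)
    if method not in SELECTOR_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SELECTOR_METHODS}")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before selection")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant")
    d = X.shape[1]
    if method == "all":
        return np.arange(d)
    if method not in ("CFS",) and k > d:
        raise ValueError(f"k={k} exceeds the number of features {d}")
    if method == "CFS":
        return _cfs(X, y)
    if method == "SVMB":
        rfe = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=k, step=1)
        rfe.fit(X, y)
        selected = np.nonzero(rfe.support_)[0]
        coefs = np.abs(np.ravel(rfe.estimator_.coef_))
        return selected[np.argsort(-coefs, kind="stable")]
    if method == "LAP":
        return _laplacian_score(X, k)

    X_bin = np.column_stack([_quantile_bin(X[:, j], n_bins) for j in range(d)])

    if method == "CMIM":
        def score(j, selected, relevance):
            return min(_cond_mi(X_bin[:, j], y, X_bin[:, s]) for s in selected)
        return _greedy_info(X_bin, y, k, score, lambda rel: rel)
    if method == "DISR":
        def score(j, selected, relevance):
            total = 0.0
            for s in selected:
                joint = _pack(X_bin[:, j], X_bin[:, s])
                h = _entropy_from_counts(np.bincount(joint).astype(float))
                total += _mi(joint, y) / max(h, 1e-12)
            return total
        hs = np.array([_entropy_from_counts(np.bincount(X_bin[:, j]).astype(float))
                       for j in range(d)])
        return _greedy_info(X_bin, y, k, score,
                            lambda rel: rel / np.maximum(hs, 1e-12))
    if method == "ICAP":
        def score(j, selected, relevance):
            penalty = sum(
                max(0.0, _mi(X_bin[:, j], X_bin[:, s])
                    - _cond_mi(X_bin[:, j], X_bin[:, s], y))
                for s in selected
            )
            return relevance[j] - penalty
        return _greedy_info(X_bin, y, k, score, lambda rel: rel)
    raise AssertionError("unreachable")


def _laplacian_score(X: np.ndarray, k: int, n_neighbors: int = 5) -> np.ndarray:
    """Laplacian score (unsupervised): features smooth over the sample kNN
    graph score low; the ``k`` lowest-scoring features are returned."""
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    t = np.mean(dist[:, 1:] ** 2) or 1.0
    n = len(X)
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx[:, 1:].ravel()
    w = np.exp(-(dist[:, 1:].ravel() ** 2) / t)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ deg) / deg.sum()
        num = f_t @ (deg * f_t) - f_t @ (W @ f_t)  # f̃ᵀ L f̃
        den = f_t @ (deg * f_t)
        scores[j] = num / den if den > 1e-12 else np.inf
    return np.argsort(scores, kind="stable")[:k]


# ---------------------------------------------------------------------------
# GraphSAGE (numpy, mean aggregator)
# ---------------------------------------------------------------------------

@dataclass
class SageConfig:
    """Hyperparameters of the GraphSAGE node classifier."""

    n_layers: int = 2
    hidden_dim: int = 64
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 300
    weight_decay: float = 1e-4
    class_weighting: bool = True
    use_edge_weights: bool = False
    val_fraction: float = 0.0       # >0 enables early stopping on a split of
                                    # the training nodes; at cohort sizes of a
                                    # few hundred the val split is too small to
                                    # stop reliably, so the default is a fixed
                                    # epoch budget
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers not in range(0, 5):
            raise ValueError("n_layers must be in 0..4")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class SageModel:
    """Mean-aggregator GraphSAGE with a linear classification head.

    Each layer computes h_v ← relu(W·[h_v ‖ mean_{u∈N(v)} h_u]); an
    isolated node's neighbourhood mean is the zero vector.  Messages flow
    over the full graph while the loss only sees masked training nodes
    (transductive masking).  With ``n_layers=0`` the model is exactly a
    logistic regression on the node features.
    """

    def __init__(self, n_features: int, cfg: SageConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        dim = n_features
        for _ in range(cfg.n_layers):
            fan_in = 2 * dim
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cfg.hidden_dim))
            self.weights.append(w)
            self.biases.append(np.zeros(cfg.hidden_dim))
            dim = cfg.hidden_dim
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / dim), size=dim)
        self.head_b = 0.0
        self._rng = rng

    def _params(self):
        return self.weights + self.biases + [self.head_w, np.atleast_1d(self.head_b)]

    def forward(self, X, A, train: bool = False):
        h = X
        cache = []
        for w, b in zip(self.weights, self.biases):
            m = A @ h
            z = np.hstack([h, m]) @ w + b
            act = np.maximum(z, 0.0)
            mask = None
            if train and self.cfg.dropout > 0:
                mask = (self._rng.uniform(size=act.shape) >= self.cfg.dropout)
                act = act * mask / (1.0 - self.cfg.dropout)
            cache.append((h, m, z, mask))
            h = act
        logits = h @ self.head_w + self.head_b
        return logits, h, cache

    def backward(self, X, A, cache, h_last, dlogits):
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        g_head_w = h_last.T @ dlogits
        g_head_b = float(dlogits.sum())
        dh = np.outer(dlogits, self.head_w)
        for li in range(len(self.weights) - 1, -1, -1):
            h_in, m_in, z, mask = cache[li]
            if mask is not None:
                dh = dh * mask / (1.0 - self.cfg.dropout)
            dz = dh * (z > 0)
            concat = np.hstack([h_in, m_in])
            grads_w[li] = concat.T @ dz
            grads_b[li] = dz.sum(axis=0)
            dcat = dz @ self.weights[li].T
            d_in = h_in.shape[1]
            dh = dcat[:, :d_in] + A.T @ dcat[:, d_in:]
        return grads_w, grads_b, g_head_w, g_head_b


def _mean_adjacency(pg: PopulationGraph, weighted: bool) -> sp.csr_matrix:
    a = pg.adjacency(weighted=weighted).astype(float)
    deg = np.asarray(a.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    return sp.diags(inv) @ a


def train_graphsage(
    pg: PopulationGraph,
    labels: np.ndarray,
    train_mask: np.ndarray,
    cfg: SageConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Train on masked nodes, return per-node class-1 probabilities.

    ``labels`` may carry any value on non-training nodes (it is never read
    there).  Training uses Adam on a weighted binary cross-entropy; a
    seeded split of the training nodes provides early stopping.  Raises
    ``RuntimeError`` if the loss diverges to NaN.
    """
    if cfg is None:
        cfg = SageConfig()
    labels = np.asarray(labels, float)
    train_mask = np.asarray(train_mask, bool)
    y_tr = labels[train_mask]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training mask must contain both classes")

    A = _mean_adjacency(pg, cfg.use_edge_weights)
    X = np.asarray(pg.X, float)
    model = SageModel(X.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)

    train_idx = np.nonzero(train_mask)[0]
    n_val = max(int(round(cfg.val_fraction * len(train_idx))), 0)
    val_idx = np.array([], int)
    fit_idx = train_idx
    if n_val >= 2:
        perm = rng.permutation(train_idx)
        cand_val, cand_fit = perm[:n_val], perm[n_val:]
        # keep both classes in the fitted part
        if len(np.unique(labels[cand_fit])) == 2:
            val_idx, fit_idx = cand_val, cand_fit

    if cfg.class_weighting:
        n1 = labels[fit_idx].sum()
        n0 = len(fit_idx) - n1
        w1 = len(fit_idx) / (2.0 * max(n1, 1))
        w0 = len(fit_idx) / (2.0 * max(n0, 1))
    else:
        w0 = w1 = 1.0

    params = model._params()
    m_adam = [np.zeros_like(p, dtype=float) for p in params]
    v_adam = [np.zeros_like(p, dtype=float) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_val, best_state, stale = np.inf, None, 0
    losses = []
    for epoch in range(cfg.epochs):
        logits, h_last, cache = model.forward(X, A, train=True)
        z = logits[fit_idx]
        yb = labels[fit_idx]
        wts = np.where(yb == 1, w1, w0)
        p = 1.0 / (1.0 + np.exp(-z))
        loss = -np.mean(wts * (yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12)))
        if not np.isfinite(loss):
            raise RuntimeError(f"divergent loss at epoch {epoch}: {loss}")
        losses.append(float(loss))

        dlogits = np.zeros_like(logits)
        dlogits[fit_idx] = wts * (p - yb) / len(fit_idx)
        gw, gb, ghw, ghb = model.backward(X, A, cache, h_last, dlogits)
        grads = gw + gb + [ghw, np.atleast_1d(ghb)]

        t = epoch + 1
        new = []
        for i, (pr, g) in enumerate(zip(params, grads)):
            g = g + cfg.weight_decay * pr
            m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * g
            v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * g**2
            mh = m_adam[i] / (1 - beta1**t)
            vh = v_adam[i] / (1 - beta2**t)
            new.append(pr - cfg.learning_rate * mh / (np.sqrt(vh) + eps))
        for w, src in zip(model.weights, new[: cfg.n_layers]):
            w[...] = src
        for b, src in zip(model.biases, new[cfg.n_layers: 2 * cfg.n_layers]):
            b[...] = src
        model.head_w[...] = new[-2]
        model.head_b = float(new[-1][0])
        params = model._params()

        if len(val_idx):
            logits_eval, _, _ = model.forward(X, A, train=False)
            zv = logits_eval[val_idx]
            yv = labels[val_idx]
            pv = 1.0 / (1.0 + np.exp(-zv))
            vloss = -np.mean(yv * np.log(pv + 1e-12) + (1 - yv) * np.log(1 - pv + 1e-12))
            if vloss < best_val - 1e-6:
                best_val, stale = vloss, 0
                best_state = [p.copy() if isinstance(p, np.ndarray) else p
                              for p in (model.weights + model.biases
                                        + [model.head_w, model.head_b])]
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        nl = cfg.n_layers
        for w, src in zip(model.weights, best_state[:nl]):
            w[...] = src
        for b, src in zip(model.biases, best_state[nl: 2 * nl]):
            b[...] = src
        model.head_w[...] = best_state[-2]
        model.head_b = best_state[-1]

    logits, _, _ = model.forward(X, A, train=False)
    probs = 1.0 / (1.0 + np.exp(-logits))
    return probs, {"losses": losses, "model": model, "epochs_run": len(losses)}


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

def train_baseline(name: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0,
                   **hyper):
    """Fit one of the five classical baselines; returns a probability-emitting
    scikit-learn estimator.  Inputs are expected standardized."""
    if name not in BASELINE_NAMES:
        raise ValueError(f"unknown baseline {name!r}; expected one of {BASELINE_NAMES}")
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if name == "LR":
        est = LogisticRegression(max_iter=2000, **hyper)
    elif name == "LDA":
        est = LinearDiscriminantAnalysis(**hyper)
    elif name == "KNN":
        est = KNeighborsClassifier(n_neighbors=hyper.pop("n_neighbors", 5), **hyper)
    elif name == "NB":
        est = GaussianNB(**hyper)
    else:  # SVM
        est = SVC(kernel="rbf", probability=True, random_state=seed, **hyper)
    est.fit(X_train, y_train)
    return est
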