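"""Feature selectors, the numpy GraphSAGE, and the classical baselines."""

import numpy as np
import pandas as pd
import pytest

from retinograph import evaluation as ev
from retinograph import graph as gr
from retinograph import models as md


def _relevance_data(n=200, d=8, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, d))
    X[:, 3] = 3.0 * (2 * y - 1) + 0.01 * rng.normal(size=n)  # near-copy of y
    return X, y


class TestFeatureSelection:
    @pytest.mark.parametrize("method", ["CFS", "CMIM", "DISR", "ICAP", "SVMB", "LAP"])
    def test_label_copy_column_ranked_first(self, method):
        X, y = _relevance_data()
        idx = md.select_features(method, X, y, k=3)
        assert idx[0] == 3

    def test_cmim_avoids_duplicated_column(self):
        # conditional MI of a duplicate given its twin is zero, so CMIM
        # must not spend its first two picks on both copies
        rng = np.random.default_rng(1)
        n = 300
        y = rng.integers(0, 2, n)
        f0 = 1.5 * (2 * y - 1) + rng.normal(size=n)
        X = np.column_stack([f0, f0, rng.normal(size=n)])
        idx = md.select_features("CMIM", X, y, k=2)
        assert not {0, 1} <= set(idx[:2])

    def test_all_is_identity(self):
        X, y = _relevance_data()
        assert np.array_equal(md.select_features("all", X, y), np.arange(X.shape[1]))

    def test_invalid_requests_rejected(self):
        X, y = _relevance_data()
        with pytest.raises(ValueError, match="exceeds"):
            md.select_features("CMIM", X, y, k=99)
        with pytest.raises(ValueError, match="constant"):
            md.select_features("CMIM", X, np.zeros(len(y)), k=2)
        with pytest.raises(ValueError, match="unknown method"):
            md.select_features("RELIEF", X, y)
        with pytest.raises(ValueError, match="missing"):
            md.select_features("CMIM", X * np.nan, y, k=2)

    def test_selection_is_deterministic(self):
        X, y = _relevance_data(seed=4)
        for method in ("CFS", "CMIM", "LAP", "SVMB"):
            a = md.select_features(method, X, y, k=4)
            b = md.select_features(method, X, y, k=4)
            assert np.array_equal(a, b), method


def _toy_graph(n=120, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(40, 80, n)
    genders = rng.choice(["male", "female"], n)
    y = rng.integers(0, 2, n)
    cohort = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                           "age": ages, "gender": genders})
    feats = pd.DataFrame({"image_id": [f"i{i}" for i in range(n)],
                          "subject_id": [f"s{i}" for i in range(n)]})
    if informative:  # one-hot of the label: memorizable
        feats["f0"] = (y == 0).astype(float)
        feats["f1"] = (y == 1).astype(float)
    else:
        feats["f0"] = rng.normal(size=n)
        feats["f1"] = rng.normal(size=n)
    return gr.build_graph(cohort, feats), y


class TestGraphSage:
    def test_memorizes_one_hot_labels(self):
        pg, y = _toy_graph()
        mask = np.ones(len(y), bool)
        cfg = md.SageConfig(epochs=200, seed=0, dropout=0.0)
        probs, _ = md.train_graphsage(pg, y, mask, cfg)
        acc = np.mean((probs >= 0.5) == y)
        assert acc >= 0.99

    def test_seeded_determinism(self):
        pg, y = _toy_graph(seed=2)
        mask = np.zeros(len(y), bool)
        mask[:80] = True
        cfg = md.SageConfig(epochs=50, seed=7)
        p1, _ = md.train_graphsage(pg, y, mask, cfg)
        p2, _ = md.train_graphsage(pg, y, mask, cfg)
        assert np.array_equal(p1, p2)

    def test_test_labels_never_read(self):
        pg, y = _toy_graph(seed=3)
        mask = np.zeros(len(y), bool)
        mask[:80] = True
        cfg = md.SageConfig(epochs=50, seed=1)
        p1, _ = md.train_graphsage(pg, y, mask, cfg)
        y_mut = y.copy()
        y_mut[~mask] = 1 - y_mut[~mask]
        p2, _ = md.train_graphsage(pg, y_mut, mask, cfg)
        assert np.array_equal(p1, p2)

    def test_zero_layer_model_matches_logistic_regression(self):
        from retinograph import synthetic as syn
        cohort, feats = syn.generate_homophily_cohort(n_subjects=120, seed=9)
        y = feats["label"].to_numpy()
        fnames = [c for c in feats.columns if c.startswith("f")]
        pg = gr.build_graph(cohort, feats, feature_names=fnames)
        X = feats[fnames].to_numpy()
        tr = np.arange(len(y)) % 3 != 0
        mu, sd = X[tr].mean(0), X[tr].std(0)
        pg.X = (X - mu) / np.where(sd > 0, sd, 1)
        cfg = md.SageConfig(n_layers=0, epochs=800, learning_rate=0.05,
                            dropout=0.0, class_weighting=False, seed=0)
        probs, _ = md.train_graphsage(pg, y, tr, cfg)
        lr = md.train_baseline("LR", pg.X[tr], y[tr])
        p_lr = lr.predict_proba(pg.X)[:, 1]
        auc_sage = ev.auc_mann_whitney(y[~tr], probs[~tr])
        auc_lr = ev.auc_mann_whitney(y[~tr], p_lr[~tr])
        assert abs(auc_sage - auc_lr) < 0.02

    def test_single_class_mask_rejected(self):
        pg, y = _toy_graph(seed=5)
        mask = np.zeros(len(y), bool)
        mask[np.nonzero(y == 1)[0][:10]] = True
        with pytest.raises(ValueError, match="both classes"):
            md.train_graphsage(pg, y, mask)

    def test_isolated_nodes_are_not_an_error(self):
        n = 40
        rng = np.random.default_rng(0)
        # ages 20 years apart and alternating genders: sparse graph with isolates
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age": 30.0 + 20.0 * np.arange(n),
            "gender": ["male" if i % 2 else "female" for i in range(n)],
        })
        feats = pd.DataFrame({
            "image_id": [f"i{i}" for i in range(n)],
            "subject_id": [f"s{i}" for i in range(n)],
            "f0": rng.normal(size=n),
        })
        pg = gr.build_graph(cohort, feats)
        y = rng.integers(0, 2, n)
        y[:4] = [0, 1, 0, 1]
        mask = np.zeros(n, bool)
        mask[:30] = True
        probs, _ = md.train_graphsage(pg, y, mask, md.SageConfig(epochs=30, seed=0))
        assert np.all(np.isfinite(probs))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            md.SageConfig(n_layers=5)
        with pytest.raises(ValueError):
            md.SageConfig(dropout=1.0)


class TestBaselines:
    def _blobs(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 2)) + 3.0 * np.column_stack([2 * y - 1, 2 * y - 1])
        return X, y

    @pytest.mark.parametrize("name", md.BASELINE_NAMES)
    def test_separable_blobs_learned(self, name):
        X, y = self._blobs()
        est = md.train_baseline(name, X[:200], y[:200], seed=0)
        acc = np.mean(est.predict(X[200:]) == y[200:])
        assert acc >= 0.95

    def test_knn_with_k_equal_n_train_is_majority_rule(self):
        X, y = self._blobs(n=200, seed=3)
        n_train = 100
        y_bal = np.r_[np.zeros(50, int), np.ones(50, int)]
        est = md.train_baseline("KNN", X[:n_train], y_bal, n_neighbors=n_train)
        preds = est.predict(X[n_train:])
        assert len(np.unique(preds)) == 1  # every prediction is the tie-break
        assert abs(np.mean(preds == y[n_train:]) - 0.5) < 0.15

    def test_gaussian_nb_boundary_matches_analytic_bayes_rule(self):
        # two independent unit-variance Gaussians with means ±1 on both axes:
        # the Bayes boundary is x1 + x2 = 0
        rng = np.random.default_rng(1)
        n = 4000
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 2)) + (2 * y - 1)[:, None]
        est = md.train_baseline("NB", X, y)
        line = np.linspace(-0.5, 0.5, 2001)
        probe = np.column_stack([line, np.zeros_like(line)])
        p = est.predict_proba(probe)[:, 1]
        crossing = line[np.argmin(np.abs(p - 0.5))]
        assert abs(crossing) < 0.1

    def test_single_class_training_rejected(self):
        X, _ = self._blobs()
        with pytest.raises(ValueError, match="single class"):
            md.train_baseline("LR", X, np.zeros(len(X), int))

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            md.train_baseline("MLP", np.zeros((4, 2)), np.array([0, 1, 0, 1]))
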