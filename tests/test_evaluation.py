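"""Cross-validation protocol, metric identities, McNemar and odds ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retinograph import evaluation as ev


def _image_table(n_subjects=60, both_eyes_p=0.6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        sid = f"s{i}"
        eyes = ["L", "R"] if rng.uniform() < both_eyes_p else ["L"]
        for e in eyes:
            rows.append({"image_id": f"{sid}_{e}", "subject_id": sid})
    table = pd.DataFrame(rows)
    subj_label = {f"s{i}": int(rng.uniform() < 0.5) for i in range(n_subjects)}
    labels = table["subject_id"].map(subj_label).to_numpy()
    return table, labels


def _dummy_fit(tr, te, rep, fold):
    rng = np.random.default_rng(rep * 100 + fold)
    return rng.uniform(size=len(te))


class TestRepeatedKfold:
    def test_every_image_predicted_once_per_repeat(self):
        table, labels = _image_table()
        preds = ev.repeated_kfold(table, labels, _dummy_fit, k=10, repeats=3, seed=0)
        for rep, g in preds.groupby("repeat"):
            assert sorted(g["image_id"]) == sorted(table["image_id"])
        assert len(preds) == 3 * len(table)

    def test_both_eyes_stay_in_the_same_fold(self):
        table, labels = _image_table(both_eyes_p=1.0)
        preds = ev.repeated_kfold(table, labels, _dummy_fit, k=10, repeats=2, seed=1)
        per = preds.groupby(["repeat", "subject_id"])["fold"].nunique()
        assert (per == 1).all()

    def test_small_class_reduces_k_with_warning(self):
        table, labels = _image_table(n_subjects=20)
        labels = np.zeros(len(table), int)
        labels[:4] = 1
        with pytest.warns(UserWarning, match="reducing k"):
            ev.repeated_kfold(table, labels, _dummy_fit, k=10, repeats=1, seed=0)


class TestMetrics:
    def test_perfect_probabilities(self):
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        p = y.astype(float)
        m = ev.compute_metrics(y, p)
        for k in ("sensitivity", "specificity", "accuracy", "auc", "f1", "precision"):
            assert m[k][0] == pytest.approx(1.0)

    def test_constant_probability_is_degenerate_all_positive(self):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        m = ev.compute_metrics(y, np.full(100, 0.7))
        assert m["sensitivity"][0] == 1.0
        assert m["specificity"][0] == 0.0
        assert m["accuracy"][0] == 0.5
        assert m["auc"][0] == 0.5

    def test_hand_counted_two_by_two(self):
        # TP=32, FN=13, TN=31, FP=13
        y = np.r_[np.ones(45, int), np.zeros(44, int)]
        p = np.r_[np.full(32, 0.9), np.full(13, 0.1), np.full(31, 0.1), np.full(13, 0.9)]
        m = ev.compute_metrics(y, p)
        assert m["sensitivity"][0] == pytest.approx(32 / 45, abs=1e-12)
        assert m["specificity"][0] == pytest.approx(31 / 44, abs=1e-12)

    def test_metric_identities(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        p = np.clip(rng.normal(0.5 + 0.2 * (y - 0.5), 0.3), 0, 1)
        m = ev.compute_metrics(y, p)
        P, N = y.sum(), (1 - y).sum()
        acc_ident = (m["sensitivity"][0] * P + m["specificity"][0] * N) / (P + N)
        assert m["accuracy"][0] == pytest.approx(acc_ident, abs=1e-12)
        prec, sens = m["precision"][0], m["sensitivity"][0]
        assert m["f1"][0] == pytest.approx(2 * prec * sens / (prec + sens), abs=1e-12)
        mid, lo, hi = m["auc"]
        assert lo <= mid <= hi

    def test_auc_equals_brute_force_concordance(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500)
        p = rng.uniform(size=500)
        p[y == 1] += 0.2 * rng.uniform(size=(y == 1).sum())
        pos, neg = p[y == 1], p[y == 0]
        brute = np.mean(
            (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        )
        assert ev.auc_mann_whitney(y, p) == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(np.ones(10, int), np.ones(10))


class TestSubjectwise:
    def test_two_eyes_averaged(self):
        preds = pd.DataFrame({
            "subject_id": ["a", "a", "b"],
            "prob": [0.6, 0.8, 0.4],
            "y": [1, 1, 0],
        })
        out = ev.subjectwise_aggregate(preds).set_index("subject_id")
        assert out.loc["a", "prob"] == pytest.approx(0.7)
        assert out.loc["b", "prob"] == pytest.approx(0.4)  # one-eye passthrough

    def test_missing_subject_mapping_rejected(self):
        preds = pd.DataFrame({"subject_id": [np.nan], "prob": [0.5], "y": [1]})
        with pytest.raises(ValueError):
            ev.subjectwise_aggregate(preds)


class TestMcNemar:
    def _construct(self, b, c, n=60):
        """Build prediction vectors with exactly b and c discordant pairs."""
        y = np.zeros(n, int)
        pa = y.copy()
        pb = y.copy()
        pa[:c] = 1          # A wrong, B right on c instances
        pb[c:c + b] = 1     # B wrong, A right on b instances
        return pa, pb, y

    def test_symmetric_discordance_gives_p_one(self):
        pa, pb, y = self._construct(5, 5)
        p, info = ev.mcnemar_test(pa, pb, y)
        assert p == pytest.approx(1.0)
        assert info["method"] == "exact-binomial"

    def test_one_sided_discordance_exact_tail(self):
        pa, pb, y = self._construct(10, 0)
        p, _ = ev.mcnemar_test(pa, pb, y)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_identical_predictions_flagged(self):
        y = np.zeros(30, int)
        p, info = ev.mcnemar_test(y, y, y)
        assert p == 1.0 and info["degenerate"]

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        pa, pb, y = self._construct(8, 3)
        p, info = ev.mcnemar_test(pa, pb, y)
        table = [[0, info["b"]], [info["c"], 0]]
        ref = sm_mcnemar(table, exact=True).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_large_discordance_uses_chi2(self):
        pa, pb, y = self._construct(20, 12)
        p, info = ev.mcnemar_test(pa, pb, y)
        assert info["method"] == "chi2-continuity"
        chi2 = (abs(20 - 12) - 1) ** 2 / 32
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)


class TestAssociation:
    def test_two_by_two_cross_product_ratio(self):
        # counts: exposed a=30 cases, b=20 controls; unexposed c=15, d=35
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(30), np.zeros(20), np.ones(15), np.zeros(35)]
        res = ev.association_or(x, y, covariates=None, standardize=False)
        assert res.converged
        assert res.odds_ratio == pytest.approx((30 * 35) / (20 * 15), rel=1e-4)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        n, sims = 1000, 200
        hits = 0
        for _ in range(sims):
            x = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            res = ev.association_or(x, y, covariates=None)
            hits += res.p_value < 0.05
        assert hits / sims == pytest.approx(0.05, abs=0.03)

    def test_constant_feature_flagged(self):
        res = ev.association_or(np.ones(50), np.r_[np.ones(25), np.zeros(25)])
        assert not res.converged

    def test_separation_flagged_not_crashed(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.astype(int)
        res = ev.association_or(x, y, covariates=None)
        assert not res.converged
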