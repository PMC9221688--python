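"""Cross-validated evaluation, metrics with confidence intervals, paired
classifier comparison, and per-feature odds-ratio association analysis.

Folds are stratified by class and grouped by subject, so the two eyes of one
subject never straddle the train/test boundary (stricter than plain
stratification; prevents within-subject leakage from inflating AUC).
Subject-wise results average the left/right eye probabilities of each
subject before thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

__all__ = [
    "repeated_kfold",
    "compute_metrics",
    "subjectwise_aggregate",
    "mcnemar_test",
    "association_or",
    "ORResult",
    "auc_mann_whitney",
    "OR_MODEL1_COVARIATES",
    "OR_MODEL2_COVARIATES",
]

OR_MODEL1_COVARIATES = ("age", "gender")
OR_MODEL2_COVARIATES = ("age", "gender", "sbp", "heart_rate", "diabetes", "bmi", "smoker")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def repeated_kfold(
    image_table: pd.DataFrame,
    labels: np.ndarray,
    fit_predict,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated stratified group k-fold out-of-fold predictions.

    ``image_table`` needs ``image_id`` and ``subject_id`` columns aligned
    with ``labels``.  ``fit_predict(train_idx, test_idx, repeat, fold)``
    must return class-1 probabilities for ``test_idx``; all preprocessing
    (standardization, feature selection) belongs inside that callable so it
    is fit on the training fold only.  Every image is predicted exactly once
    per repeat; each repeat reshuffles with a fresh derived seed.
    """
    labels = np.asarray(labels).astype(int)
    groups = image_table["subject_id"].to_numpy()
    counts = np.bincount(labels, minlength=2)
    k_eff = k
    min_groups = min(
        pd.Series(groups[labels == c]).nunique() for c in np.unique(labels)
    )
    if min_groups < k:
        k_eff = max(int(min_groups), 2)
        warnings.warn(f"class has only {min_groups} subject groups; reducing k to {k_eff}")
    del counts

    rows = []
    for rep in range(repeats):
        splitter = StratifiedGroupKFold(n_splits=k_eff, shuffle=True,
                                        random_state=seed + 1000 * rep)
        for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(labels)), labels, groups)):
            probs = np.asarray(fit_predict(tr, te, rep, fold), float)
            if len(probs) != len(te):
                raise ValueError("fit_predict returned wrong number of probabilities")
            for idx, p in zip(te, probs):
                rows.append({
                    "image_id": image_table["image_id"].iloc[idx],
                    "subject_id": image_table["subject_id"].iloc[idx],
                    "y": int(labels[idx]),
                    "prob": float(p),
                    "repeat": rep,
                    "fold": fold,
                })
    preds = pd.DataFrame(rows)
    per_rep = preds.groupby("repeat")["image_id"].count()
    assert (per_rep == len(labels)).all(), "each image must be predicted once per repeat"
    return preds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_mann_whitney(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """AUC by the Mann–Whitney U formulation (tie-aware rank statistic)."""
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_prob, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _hanley_mcneil_ci(auc: float, n1: int, n0: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    return float(np.clip(auc - 1.96 * se, 0, 1)), float(np.clip(auc + 1.96 * se, 0, 1))


def _wilson(successes: int, total: int) -> tuple[float, float]:
    if total == 0:
        return 0.0, 1.0
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def compute_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5, seed: int = 0
) -> dict:
    """Sensitivity, specificity, accuracy, AUC, F1 and precision with 95% CIs.

    Proportion CIs use the Wilson score interval; the AUC CI uses the
    Hanley–McNeil variance; the F1 CI is a seeded percentile bootstrap
    (500 resamples), since F1 is not a plain proportion.
    Each entry is ``(point, ci_low, ci_high)``.
    """
    y = np.asarray(y_true).astype(int)
    p = np.asarray(y_prob, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = auc_mann_whitney(y, p)

    def f1_of(yy, pp):
        predb = (pp >= threshold).astype(int)
        tpb = np.sum((predb == 1) & (yy == 1))
        fpb = np.sum((predb == 1) & (yy == 0))
        fnb = np.sum((predb == 0) & (yy == 1))
        denom = 2 * tpb + fpb + fnb
        return 2 * tpb / denom if denom else 0.0

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(500):
        idx = rng.integers(0, len(y), len(y))
        boot.append(f1_of(y[idx], p[idx]))
    f1_lo, f1_hi = np.percentile(boot, [2.5, 97.5])

    return {
        "sensitivity": (sens, *_wilson(tp, tp + fn)),
        "specificity": (spec, *_wilson(tn, tn + fp)),
        "accuracy": (acc, *_wilson(tp + tn, len(y))),
        "auc": (auc, *_hanley_mcneil_ci(auc, tp + fn, tn + fp)),
        "f1": (f1, float(f1_lo), float(f1_hi)),
        "precision": (prec, *_wilson(tp, tp + fp)) if tp + fp else (0.0, 0.0, 1.0),
        "counts": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }


def subjectwise_aggregate(predictions: pd.DataFrame, cohort: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Average each subject's available eye probabilities (per repeat).

    One-eye subjects pass through unchanged.  ``predictions`` needs
    ``subject_id``, ``prob`` and ``y`` columns (plus optional ``repeat``).
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to aggregate")
    if predictions["subject_id"].isna().any():
        raise ValueError("predictions with missing subject mapping")
    keys = ["subject_id"] + (["repeat"] if "repeat" in predictions else [])
    out = predictions.groupby(keys, as_index=False).agg(
        prob=("prob", "mean"), y=("y", "first"), n_eyes=("prob", "size")
    )
    return out


# ---------------------------------------------------------------------------
# Paired comparison and association
# ---------------------------------------------------------------------------

def mcnemar_test(pred_a: np.ndarray, pred_b: np.ndarray, y_true: np.ndarray
                 ) -> tuple[float, dict]:
    """McNemar's test on the discordant pairs of two classifiers.

    b = instances A classifies correctly and B incorrectly; c = the reverse.
    Exact binomial when b + c < 25, else the continuity-corrected
    chi-square.  b = c = 0 (no discordance) is degenerate: p = 1.0 with a
    flag.  Returns ``(p_value, info)``.
    """
    a_right = np.asarray(pred_a).astype(int) == np.asarray(y_true).astype(int)
    b_right = np.asarray(pred_b).astype(int) == np.asarray(y_true).astype(int)
    if len(a_right) != len(b_right):
        raise ValueError("paired predictions must have equal length")
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    info = {"b": b, "c": c, "degenerate": False, "method": None}
    if b + c == 0:
        info.update(degenerate=True, method="degenerate")
        return 1.0, info
    if b + c < 25:
        info["method"] = "exact-binomial"
        p = stats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue
    else:
        info["method"] = "chi2-continuity"
        chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
        p = float(stats.chi2.sf(chi2, df=1))
    return float(min(p, 1.0)), info


@dataclass
class ORResult:
    """Per-SD odds ratio of one biomarker from adjusted logistic regression."""

    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjustment: tuple
    converged: bool = True
    note: str = ""


def association_or(
    feature: str | np.ndarray,
    label: np.ndarray,
    covariates: pd.DataFrame | None = None,
    data: pd.DataFrame | None = None,
    adjustment: tuple = OR_MODEL1_COVARIATES,
    standardize: bool = True,
) -> ORResult:
    """Odds ratio of a biomarker for the binary label, covariate-adjusted.

    The biomarker is standardized so the OR is per standard deviation
    (``standardize=False`` reports the OR per raw unit instead, e.g. for a
    binary exposure).
    Fitted by iteratively reweighted least squares (binomial GLM); Wald 95%
    CI and p-value.  Separation or non-convergence yields a flagged result
    with no OR.
    """
    if isinstance(feature, str):
        if data is None:
            raise ValueError("pass `data` when `feature` is a column name")
        fname = feature
        x = data[feature].to_numpy(float)
        if covariates is None:
            cov = pd.DataFrame(index=data.index)
            for c in adjustment:
                col = data[c]
                if col.dtype == object or col.dtype == bool:
                    col = pd.factorize(col)[0]
                cov[c] = np.asarray(col, float)
            covariates = cov
    else:
        fname = "feature"
        x = np.asarray(feature, float)
    y = np.asarray(label).astype(float)
    sd = x.std(ddof=0)
    if sd == 0:
        return ORResult(fname, np.nan, np.nan, np.nan, np.nan, adjustment,
                        converged=False, note="constant feature")
    xs = (x - x.mean()) / sd if standardize else x
    design = pd.DataFrame({"const": 1.0, fname: xs})
    if covariates is not None:
        for c in covariates.columns:
            design[c] = np.asarray(covariates[c], float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, design.to_numpy(), family=sm.families.Binomial()).fit(
                maxiter=100
            )
        beta = fit.params[1]
        se = fit.bse[1]
        if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
            raise ValueError("separation suspected (unstable standard error)")
    except Exception as exc:
        return ORResult(fname, np.nan, np.nan, np.nan, np.nan, adjustment,
                        converged=False, note=str(exc))
    return ORResult(
        feature=fname,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        adjustment=tuple(adjustment),
    )
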