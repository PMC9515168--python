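"""Repeated cross-validation, AUROC/RMSE metrics, and per-group breakdowns.

AUROC is computed in its Mann-Whitney formulation — the probability that a
random positive outranks a random negative, ties counted one half. Model
comparison across the k x r fold scores uses the two-sided Mann-Whitney U
test (exact for small samples). Per-drug and per-cancer breakdowns are
computed on pooled out-of-fold predictions, restricted to groups with at
least ``min_group_n`` samples, and averaged separately for groups present
vs absent in the source (cell-line) panel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from pathdrp.model_core import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "auroc", "rmse", "repeated_cv", "per_group_performance", "compare_models"]


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative
    (rank-sum formulation; ties count 1/2)."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


@dataclasses.dataclass
class CVResult:
    """k x r fold scores plus pooled out-of-fold predictions."""

    fold_scores: np.ndarray  # shape (repeats, k)
    predictions: pd.DataFrame  # sample_id, drug_id, cancer_type?, y_true, y_pred
    metric: str

    @property
    def mean(self) -> float:
        return float(self.fold_scores.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_scores.std(ddof=1))

    def summary(self) -> str:
        return f"{self.mean:.3f} ± {self.sd:.3f}"


def _stratified_folds(
    table: FeatureTable, k: int, rng_seed: int, task: str, max_attempts: int = 10
):
    """Fold index pairs; stratified by (drug, label) for classification."""
    n = table.n_rows
    if n < k:
        raise ValueError(f"{n} rows cannot make {k} folds")
    if task == "classification":
        strata = np.array([f"{d}|{y:g}" for d, y in zip(table.drug_ids, table.y)])
        for attempt in range(max_attempts):
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed + attempt)
            folds = list(splitter.split(np.zeros(n), strata))
            ok = all(len(np.unique(table.y[te])) == 2 for _, te in folds)
            if ok:
                if attempt:
                    logger.warning("re-drew folds %d time(s) to keep both classes", attempt)
                return folds
        raise ValueError(f"could not draw folds with both classes in {max_attempts} attempts")
    splitter = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return list(splitter.split(np.zeros(n)))


def repeated_cv(
    fit_predict,
    table: FeatureTable,
    task: str,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation repeated ``repeats`` times (k*r fold scores).

    ``fit_predict(train_table, test_table) -> scores`` trains from scratch on
    each training fold and returns test predictions (probabilities for
    classification). The metric is AUROC for classification, RMSE for
    regression.
    """
    if task not in ("classification", "regression"):
        raise ValueError(f"unknown task {task!r}")
    scores = np.empty((repeats, k))
    pred_rows = []
    for r in range(repeats):
        folds = _stratified_folds(table, k, seed * 1000 + r, task)
        for f, (tr, te) in enumerate(folds):
            train_t = table.subset(tr)
            test_t = table.subset(te)
            y_pred = np.asarray(fit_predict(train_t, test_t), dtype=float)
            if task == "classification":
                scores[r, f] = auroc(test_t.y, y_pred)
            else:
                scores[r, f] = rmse(test_t.y, y_pred)
            for i in range(test_t.n_rows):
                pred_rows.append(
                    {
                        "repeat": r,
                        "fold": f,
                        "sample_id": test_t.sample_ids[i],
                        "drug_id": test_t.drug_ids[i],
                        "y_true": float(test_t.y[i]),
                        "y_pred": float(y_pred[i]),
                    }
                )
    return CVResult(scores, pd.DataFrame(pred_rows), "auroc" if task == "classification" else "rmse")


def per_group_performance(
    predictions: pd.DataFrame,
    group_by: str,
    membership: dict[str, bool] | None = None,
    min_group_n: int = 5,
    metric: str = "auroc",
) -> pd.DataFrame:
    """Metric per group (drug or cancer type) on pooled predictions.

    Groups with fewer than ``min_group_n`` distinct samples are excluded;
    groups where the metric is undefined (single class) are excluded with a
    warning. ``membership`` flags groups present in the source panel so
    member / non-member means can be compared.
    """
    if group_by not in predictions.columns:
        raise ValueError(f"missing grouping column {group_by!r}")
    rows = []
    for g, sub in predictions.groupby(group_by, sort=True):
        n = sub["sample_id"].nunique()
        if n < min_group_n:
            continue
        try:
            if metric == "auroc":
                value = auroc(sub["y_true"].to_numpy(), sub["y_pred"].to_numpy())
            else:
                value = rmse(sub["y_true"].to_numpy(), sub["y_pred"].to_numpy())
        except ValueError:
            logger.warning("group %r: metric undefined (single class); excluded", g)
            continue
        rows.append(
            {
                group_by: g,
                "n_samples": n,
                metric: value,
                "in_source_panel": bool(membership.get(g, False)) if membership else None,
            }
        )
    if not rows:
        logger.warning("no group survives the min_group_n=%d filter", min_group_n)
        return pd.DataFrame(columns=[group_by, "n_samples", metric, "in_source_panel"])
    return pd.DataFrame(rows)


def compare_models(fold_scores_a: np.ndarray, fold_scores_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value between two sets of fold scores;
    exact when both sides have <= 8 scores, normal approximation with tie
    correction otherwise."""
    a = np.asarray(fold_scores_a, dtype=float).ravel()
    b = np.asarray(fold_scores_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty fold-score input")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 scores per side")
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not _has_ties(a, b)) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    joint = np.concatenate([a, b])
    return len(np.unique(joint)) != len(joint)
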