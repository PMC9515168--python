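"""Shapley-value attribution and responder vs non-responder pathway tests.

Attributions are estimated by permutation sampling against a baseline set:
for each Monte-Carlo draw, features flip from a baseline row to the
explained row in a random order and each feature is credited its marginal
change in model output. Summed over features this telescopes to
f(x) - f(baseline), so efficiency holds by construction; baselines are
cycled deterministically so the average matches the full baseline set.
When the feature count is at most 12, exact enumeration over all feature
subsets is used instead.

Feature importance is the mean absolute Shapley value across samples.
Responder vs non-responder comparisons use the two-sided Mann-Whitney U
test per pathway with Benjamini-Hochberg FDR control; responders and
non-responders are defined as true positives and true negatives of the
classifier, the samples the model labels confidently and correctly.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionMatrix",
    "GroupComparison",
    "shapley_values",
    "rank_importance",
    "compare_groups",
    "categorize_predictions",
]


@dataclasses.dataclass
class AttributionMatrix:
    values: pd.DataFrame  # samples x features of Shapley values
    baseline_output: float  # mean model output over the baseline set

    @property
    def importance(self) -> pd.Series:
        """Mean |Shapley value| per feature across samples."""
        return self.values.abs().mean(axis=0)


@dataclasses.dataclass
class GroupComparison:
    table: pd.DataFrame  # pathway, u_stat, p, q, significant
    alpha: float


def _exact_shapley(
    model_fn, X: np.ndarray, baselines: np.ndarray
) -> np.ndarray:
    """Exact Shapley values by subset enumeration (feature count <= 12)."""
    n, d = X.shape
    subsets = list(itertools.product([0, 1], repeat=d))
    weights = {}
    for s in range(d):
        weights[s] = math.factorial(s) * math.factorial(d - s - 1) / math.factorial(d)
    phi = np.zeros((n, d))
    for b in baselines:
        # evaluate model on every masked combination for all samples at once
        masks = np.array(subsets, dtype=bool)  # 2^d x d
        for i in range(n):
            inputs = np.where(masks, X[i], b)
            outputs = np.asarray(model_fn(inputs), dtype=float)
            val = {tuple(m): outputs[k] for k, m in enumerate(masks.astype(int))}
            for j in range(d):
                for m in subsets:
                    if m[j] == 1:
                        continue
                    m_with = tuple(1 if t == j else m[t] for t in range(d))
                    phi[i, j] += weights[sum(m)] * (val[m_with] - val[m])
    return phi / len(baselines)


def shapley_values(
    model_fn,
    X: np.ndarray,
    feature_names: list[str],
    baselines: np.ndarray,
    n_samples_per_feature: int = 20,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> AttributionMatrix:
    """Per-(sample, feature) Shapley attribution of ``model_fn`` outputs.

    ``model_fn`` maps an (n, d) array to n outputs (probabilities for a
    classifier). ``baselines`` is the non-empty reference set (e.g. 100
    seeded training rows). The Monte-Carlo draw count is rounded up to a
    multiple of the baseline count so that efficiency holds against the
    full-set baseline mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    baselines = np.atleast_2d(np.asarray(baselines, dtype=float))
    if baselines.shape[0] == 0:
        raise ValueError("baseline set must be non-empty")
    n, d = X.shape
    if baselines.shape[1] != d:
        raise ValueError("baseline/feature dimension mismatch")
    if len(feature_names) != d:
        raise ValueError("feature_names length mismatch")

    base_out = float(np.mean(np.asarray(model_fn(baselines), dtype=float)))

    if d <= 12:
        phi = _exact_shapley(model_fn, X, baselines)
    else:
        rng = np.random.default_rng(seed)
        n_b = baselines.shape[0]
        n_iter = max(1, int(math.ceil(n_samples_per_feature / n_b))) * n_b
        phi = np.zeros((n, d))
        for it in range(n_iter):
            b = baselines[it % n_b]
            perm = rng.permutation(d)
            # walk b -> x along perm for every sample; one batched forward pass
            steps = np.tile(b, (n, d + 1, 1))
            for pos, j in enumerate(perm):
                steps[:, pos + 1 :, j] = X[:, j, None]
            outs = np.asarray(
                model_fn(steps.reshape(n * (d + 1), d)), dtype=float
            ).reshape(n, d + 1)
            phi[:, perm] += outs[:, 1:] - outs[:, :-1]
        phi /= n_iter

    index = sample_ids if sample_ids is not None else list(range(n))
    return AttributionMatrix(pd.DataFrame(phi, index=index, columns=feature_names), base_out)


def rank_importance(att: AttributionMatrix, top_k: int) -> pd.Series:
    """Features sorted by mean |Shapley| descending (ties lexicographic);
    the top ``top_k`` are returned with their importance values."""
    if att.values.empty:
        raise ValueError("empty attribution matrix")
    imp = att.importance
    if top_k > len(imp):
        logger.warning("top_k=%d exceeds feature count %d; truncated", top_k, len(imp))
        top_k = len(imp)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order[:top_k]]


def compare_groups(
    scores: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Per-pathway two-sided Mann-Whitney U between two sample groups with
    Benjamini-Hochberg step-up FDR adjustment; significant at q < alpha.

    ``scores`` is a samples x pathways frame (e.g. ssGSEA enrichment
    scores); groups are disjoint sample-id lists with >= 3 samples each.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("groups overlap")
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValueError("both groups need >= 3 samples")
    a = scores.loc[sorted(set_a)]
    b = scores.loc[sorted(set_b)]
    rows = []
    for pw in scores.columns:
        res = mannwhitneyu(a[pw], b[pw], alternative="two-sided")
        rows.append({"pathway": pw, "u_stat": float(res.statistic), "p": float(res.pvalue)})
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    table["significant"] = table["q"] < alpha
    return GroupComparison(table, alpha)


def categorize_predictions(
    labels: np.ndarray,
    probs: np.ndarray,
    sample_ids: list[str],
    threshold: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split samples into true positives (label 1, prob >= threshold) and
    true negatives (label 0, prob < threshold)."""
    labels = np.asarray(labels, dtype=float)
    probs = np.asarray(probs, dtype=float)
    tp = [s for s, y, p in zip(sample_ids, labels, probs) if y == 1.0 and p >= threshold]
    tn = [s for s, y, p in zip(sample_ids, labels, probs) if y == 0.0 and p < threshold]
    if not tp or not tn:
        logger.warning("empty TP or TN set (|TP|=%d, |TN|=%d)", len(tp), len(tn))
    return tp, tn
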