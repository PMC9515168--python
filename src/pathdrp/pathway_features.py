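"""Single-sample GSEA pathway activity scores (the EXP feature block).

For each sample, genes are ranked by expression in descending order. Walking
down the ranked list, an in-set running fraction (weighted by the
rank-normalized expression value raised to ``weight_exponent``) is compared
with the uniform out-of-set fraction; the enrichment score is the integral
(sum) of that running difference — the single-sample variant of GSEA — or,
optionally, its maximum deviation (the classic two-group GSEA statistic).

Significance is available through a membership-permutation test: the score
of each pathway is compared against scores of random gene sets of the same
size drawn from the ranked universe.

Ties in expression are broken by a seeded shuffle of the gene order so that
scoring is deterministic yet unbiased toward input order.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from pathdrp.io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["PathwayScoreMatrix", "ssgsea_score", "ssgsea_matrix", "permutation_significance"]


@dataclasses.dataclass
class PathwayScoreMatrix:
    """samples x pathways enrichment scores (+ optional permutation p-values)."""

    scores: pd.DataFrame
    p_values: pd.DataFrame | None = None

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def _ranked_order(values: np.ndarray, tie_seed: int = 0) -> np.ndarray:
    """Indices sorting ``values`` descending; ties broken by a seeded shuffle."""
    rng = np.random.default_rng(tie_seed)
    perm = rng.permutation(len(values))
    order_within = np.argsort(-values[perm], kind="stable")
    return perm[order_within]


def _integral_from_positions(
    positions: np.ndarray, weights_at: np.ndarray, n: int
) -> float:
    """Closed form of the summed running-sum statistic.

    ``positions`` are the 0-based ranks of in-set genes, ``weights_at`` the
    corresponding |rank-normalized value|^alpha weights. Equivalent to the
    explicit walk: sum_k [P_in(k) - P_out(k)].
    """
    m = len(positions)
    w_total = weights_at.sum()
    if w_total <= 0:
        w_total = 1.0
    tail = n - positions.astype(float)  # number of k >= position
    p_in_integral = (weights_at * tail).sum() / w_total
    all_tail = n * (n + 1) / 2.0
    p_out_integral = (all_tail - tail.sum()) / (n - m)
    return float(p_in_integral - p_out_integral)


def ssgsea_score(
    expression: pd.Series,
    gene_set: set[str],
    weight_exponent: float = 0.25,
    score: str = "integral",
    tie_seed: int = 0,
) -> float:
    """Enrichment score of one gene set in one sample.

    ``score="integral"`` (default) integrates the running sum — the
    single-sample statistic; ``score="max"`` returns the maximum signed
    deviation (classic GSEA). weight_exponent = 0 makes the in-set weights
    uniform, so the score depends on expression only through ranks.
    """
    genes = np.asarray(expression.index)
    values = expression.to_numpy(dtype=float)
    n = len(genes)
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has zero overlap with the expression vector")
    if m == n:
        raise ValueError("gene set covers the entire universe (degenerate complement)")

    order = _ranked_order(values, tie_seed)
    in_sorted = in_set[order]
    rank_norm = (n - np.arange(n)) / n  # descending rank, normalized to (0, 1]
    weights = rank_norm**weight_exponent

    if score == "integral":
        positions = np.flatnonzero(in_sorted)
        return _integral_from_positions(positions, weights[positions], n)
    if score == "max":
        w_in = np.where(in_sorted, weights, 0.0)
        p_in = np.cumsum(w_in) / max(w_in.sum(), 1e-300)
        p_out = np.cumsum(~in_sorted) / (n - m)
        diff = p_in - p_out
        return float(diff[np.argmax(np.abs(diff))])
    raise ValueError(f"unknown score mode {score!r}")


def ssgsea_matrix(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    weight_exponent: float = 0.25,
    normalize: bool = False,
    min_overlap: int = 5,
    score: str = "integral",
    tie_seed: int = 0,
) -> PathwayScoreMatrix:
    """Score every (sample, pathway) pair.

    Pathways overlapping the gene universe by fewer than ``min_overlap``
    genes are dropped with a warning. With ``normalize`` the whole score
    matrix is divided by its value range (max - min).
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(matrix.gene_ids)
    kept = []
    for name in collection.names:
        overlap = len(collection[name] & universe)
        if overlap >= min_overlap and overlap < len(universe):
            kept.append(name)
        else:
            logger.warning("dropping pathway %r (overlap %d)", name, overlap)
    if not kept:
        raise ValueError("no pathway passes the minimum-overlap filter")

    genes = np.asarray(matrix.gene_ids)
    n = len(genes)
    rank_norm = (n - np.arange(n)) / n
    weights_by_rank = rank_norm**weight_exponent
    member = {name: np.isin(genes, list(collection[name])) for name in kept}

    out = np.empty((matrix.n_samples, len(kept)))
    for j in range(matrix.n_samples):
        order = _ranked_order(matrix.values[:, j], tie_seed)
        for c, name in enumerate(kept):
            in_sorted = member[name][order]
            positions = np.flatnonzero(in_sorted)
            out[j, c] = _integral_from_positions(
                positions, weights_by_rank[positions], n
            )
    if normalize:
        rng_span = out.max() - out.min()
        if rng_span > 0:
            out = out / rng_span
    return PathwayScoreMatrix(pd.DataFrame(out, index=matrix.sample_ids, columns=kept))


def permutation_significance(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight_exponent: float = 0.25,
    min_overlap: int = 5,
    seed: int = 0,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Membership-permutation p-values per (sample, pathway).

    p = (1 + #{permuted-set score >= observed}) / (1 + n_perm), permuting
    gene membership at fixed set size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scored = ssgsea_matrix(
        matrix, collection, weight_exponent, False, min_overlap, "integral", tie_seed
    )
    kept = scored.pathway_names
    sizes = {name: len(collection[name] & set(matrix.gene_ids)) for name in kept}
    genes = np.asarray(matrix.gene_ids)
    n = len(genes)
    rank_norm = (n - np.arange(n)) / n
    weights_by_rank = rank_norm**weight_exponent

    rng = np.random.default_rng(seed)
    # one bank of permuted position-sets per distinct set size, shared by all
    # samples: positions are uniform on the ranked list either way
    by_size: dict[int, np.ndarray] = {}
    for m in sorted(set(sizes.values())):
        draws = np.empty((n_perm, m), dtype=int)
        for t in range(n_perm):
            draws[t] = rng.choice(n, size=m, replace=False)
        by_size[m] = draws

    tail_all = n * (n + 1) / 2.0
    null_by_size: dict[int, np.ndarray] = {}
    for m, draws in by_size.items():
        w = weights_by_rank[draws]
        tail = n - draws.astype(float)
        p_in = (w * tail).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)
        p_out = (tail_all - tail.sum(axis=1)) / (n - m)
        null_by_size[m] = np.sort(p_in - p_out)

    p = np.empty((matrix.n_samples, len(kept)))
    for c, name in enumerate(kept):
        null = null_by_size[sizes[name]]
        obs = scored.scores[name].to_numpy()
        # count of null >= obs via sorted null
        n_ge = n_perm - np.searchsorted(null, obs, side="left")
        p[:, c] = (1.0 + n_ge) / (1.0 + n_perm)
    return pd.DataFrame(p, index=matrix.sample_ids, columns=kept)
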