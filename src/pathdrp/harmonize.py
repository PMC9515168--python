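"""Cross-dataset expression harmonization.

Three steps, each dataset treated as a batch:

1. restrict all matrices to the common gene set;
2. standardize gene-wise on the pooled matrix (mean 0, sd 1, sample sd);
3. estimate per-batch location/scale random effects with the parametric
   empirical-Bayes model of Johnson, Li & Rabinovic (2007) — normal prior on
   additive effects, inverse-gamma on multiplicative — and adjust.

The adjusted value for sample j of batch b at gene g is
(z_bjg - gamma*_bg) / sqrt(delta*_bg), mapped back to the original scale
through the stored gene-wise mean/sd. Covariates (e.g. cancer type) are not
modelled: the correction is batch-only.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from pathdrp.io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BatchModel",
    "intersect_genes",
    "standardize_genewise",
    "fit_combat",
    "apply_combat",
    "harmonize_run",
]


@dataclasses.dataclass
class BatchModel:
    """Fitted batch-adjustment parameters.

    gamma_star / delta_star are (n_batches x n_genes) EB-shrunken additive
    and multiplicative effect estimates on the standardized scale;
    grand_mean / pooled_sd map back to the original expression scale.
    """

    batches: list[str]
    gene_ids: list[str]
    gamma_star: np.ndarray
    delta_star: np.ndarray
    gamma_bar: np.ndarray  # per-batch prior mean of additive effects
    tau_sq: np.ndarray  # per-batch prior variance of additive effects
    lam: np.ndarray  # inverse-gamma shape per batch
    theta: np.ndarray  # inverse-gamma scale per batch
    grand_mean: np.ndarray
    pooled_sd: np.ndarray

    def __post_init__(self) -> None:
        if (self.delta_star <= 0).any():
            raise ValueError("delta_star must be positive")


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the sorted intersection of their gene sets."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across matrices")
    order = sorted(common)
    return [m.subset_genes(order) for m in matrices]


def concat_samples(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices sharing an identical gene order."""
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise ValueError("gene order mismatch; run intersect_genes first")
    return ExpressionMatrix(
        np.hstack([m.values for m in matrices]),
        genes,
        sum((m.sample_ids for m in matrices), []),
        sum((m.batch for m in matrices), []),
        sum((m.cancer_type for m in matrices), []),
    )


def standardize_genewise(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Scale every gene row to mean 0, sd 1 (sample sd, ddof=1).

    Zero-variance genes are dropped with a warning; returns the standardized
    matrix and a per-gene (mean, sd) frame for the retained genes.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization needs at least two samples")
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    if not keep.all():
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:5])
    values = (matrix.values[keep] - mean[keep, None]) / sd[keep, None]
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    stats = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]}, index=genes)
    out = ExpressionMatrix(values, genes, matrix.sample_ids, matrix.batch, matrix.cancer_type)
    return out, stats


def _batch_groups(matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for j, b in enumerate(matrix.batch):
        groups.setdefault(b, []).append(j)
    return {b: np.array(idx) for b, idx in sorted(groups.items())}


def fit_combat(
    matrix: ExpressionMatrix,
    gene_stats: pd.DataFrame | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> BatchModel:
    """Fit parametric EB batch effects on a (standardized) matrix.

    Method-of-moments hyperpriors — normal on the per-batch-per-gene
    additive effect, inverse-gamma on the multiplicative — followed by the
    iterative conditional estimates of gamma* and delta* to ``tol``.
    When a hyperprior is degenerate (fewer than two genes, or zero spread of
    the per-gene estimates) the batch falls back to the unshrunken estimates.
    """
    groups = _batch_groups(matrix)
    if len(groups) < 2:
        raise ValueError(f"need >= 2 batches, got {len(groups)}")
    for b, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has a single sample")

    n_genes = matrix.n_genes
    batches = list(groups)
    gamma_hat = np.zeros((len(batches), n_genes))
    delta_hat = np.zeros((len(batches), n_genes))
    for i, b in enumerate(batches):
        sub = matrix.values[:, groups[b]]
        gamma_hat[i] = sub.mean(axis=1)
        delta_hat[i] = sub.var(axis=1, ddof=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1) if n_genes > 1 else np.zeros(len(batches))
    v_bar = delta_hat.mean(axis=1)
    s_sq = delta_hat.var(axis=1, ddof=1) if n_genes > 1 else np.zeros(len(batches))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (v_bar**2 + 2 * s_sq) / s_sq
        theta = (v_bar**3 + v_bar * s_sq) / s_sq

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for i, b in enumerate(batches):
        if n_genes < 2 or tau_sq[i] <= 0 or s_sq[i] <= 0:
            logger.warning("batch %r: degenerate hyperprior, no EB shrinkage", b)
            continue
        sub = matrix.values[:, groups[b]]
        n_b = sub.shape[1]
        g_star = gamma_hat[i].copy()
        d_star = delta_hat[i].copy()
        for _ in range(max_iter):
            g_new = (n_b * tau_sq[i] * gamma_hat[i] + d_star * gamma_bar[i]) / (
                n_b * tau_sq[i] + d_star
            )
            sse = ((sub - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[i] + 0.5 * sse) / (n_b / 2 + lam[i] - 1)
            change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        gamma_star[i] = g_star
        delta_star[i] = np.maximum(d_star, 1e-12)

    if gene_stats is None:
        grand_mean = np.zeros(n_genes)
        pooled_sd = np.ones(n_genes)
    else:
        grand_mean = gene_stats["mean"].to_numpy()
        pooled_sd = gene_stats["sd"].to_numpy()

    return BatchModel(
        batches=batches,
        gene_ids=list(matrix.gene_ids),
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        lam=lam,
        theta=theta,
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
    )


def apply_combat(matrix: ExpressionMatrix, model: BatchModel) -> ExpressionMatrix:
    """Adjust a standardized matrix with fitted batch effects and map back
    to the original expression scale."""
    if matrix.gene_ids != model.gene_ids:
        raise ValueError("gene order mismatch between matrix and batch model")
    unknown = set(matrix.batch) - set(model.batches)
    if unknown:
        raise ValueError(f"unknown batch label(s): {sorted(unknown)}")
    batch_index = {b: i for i, b in enumerate(model.batches)}
    adjusted = np.empty_like(matrix.values)
    for j, b in enumerate(matrix.batch):
        i = batch_index[b]
        adjusted[:, j] = (matrix.values[:, j] - model.gamma_star[i]) / np.sqrt(
            model.delta_star[i]
        )
    adjusted = adjusted * model.pooled_sd[:, None] + model.grand_mean[:, None]
    return ExpressionMatrix(
        adjusted, matrix.gene_ids, matrix.sample_ids, matrix.batch, matrix.cancer_type
    )


def harmonize_run(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Full harmonization: intersect -> concatenate -> standardize -> EB fit
    -> adjust. Batch labels are preserved in the joint output."""
    common = intersect_genes(matrices)
    joint = concat_samples(common)
    standardized, stats = standardize_genewise(joint)
    model = fit_combat(standardized, gene_stats=stats)
    return apply_combat(standardized, model)
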