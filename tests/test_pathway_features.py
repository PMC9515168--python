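"""ssGSEA: brute-force running-sum oracle, rank invariances, permutation
significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathdrp.datagen import SimulationConfig, generate_cohort
from pathdrp.harmonize import harmonize_run
from pathdrp.pathway_features import (
    permutation_significance,
    ssgsea_matrix,
    ssgsea_score,
)


def running_sum_oracle(expression: pd.Series, gene_set, alpha):
    """Step-by-step enumeration of the integrated running-sum statistic."""
    genes = list(expression.index)
    vals = expression.to_numpy(dtype=float)
    n = len(genes)
    order = np.argsort(-vals)  # callers guarantee tie-free values
    hit_weight = 0.0
    total_weight = 0.0
    for pos, idx in enumerate(order):
        if genes[idx] in gene_set:
            total_weight += ((n - pos) / n) ** alpha
    m = sum(1 for g in genes if g in gene_set)
    p_hit = 0.0
    p_miss = 0.0
    es = 0.0
    for pos, idx in enumerate(order):
        if genes[idx] in gene_set:
            p_hit += ((n - pos) / n) ** alpha / total_weight
        else:
            p_miss += 1.0 / (n - m)
        es += p_hit - p_miss
    return es


def _random_sample(rng, n=10):
    genes = [f"G{i}" for i in range(n)]
    return pd.Series(rng.normal(size=n), index=genes)


def test_score_matches_running_sum_oracle_weighted_and_unweighted():
    rng = np.random.default_rng(5)
    for _ in range(10):
        expr = _random_sample(rng)
        for alpha in (0.0, 0.25, 1.0):
            gene_set = set(rng.choice(expr.index, size=4, replace=False))
            mine = ssgsea_score(expr, gene_set, weight_exponent=alpha)
            oracle = running_sum_oracle(expr, gene_set, alpha)
            assert mine == pytest.approx(oracle, abs=1e-9)


def test_top_set_scores_higher_than_bottom_set():
    expr = pd.Series(np.arange(10, 0, -1, dtype=float), index=[f"G{i}" for i in range(10)])
    top = ssgsea_score(expr, {"G0", "G1", "G2"}, weight_exponent=0.25)
    bottom = ssgsea_score(expr, {"G7", "G8", "G9"}, weight_exponent=0.25)
    assert top > bottom


def test_gene_label_permutation_invariance():
    rng = np.random.default_rng(8)
    expr = _random_sample(rng)
    gene_set = {"G1", "G4", "G7"}
    score = ssgsea_score(expr, gene_set, weight_exponent=0.25)
    mapping = {g: f"X{g}" for g in expr.index}
    renamed = pd.Series(expr.to_numpy(), index=[mapping[g] for g in expr.index])
    renamed_set = {mapping[g] for g in gene_set}
    assert ssgsea_score(renamed, renamed_set, 0.25) == pytest.approx(score, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rank_only_dependence_at_zero_exponent(seed):
    """With exponent 0, any strictly monotone transform of expression leaves
    the score unchanged."""
    rng = np.random.default_rng(seed)
    expr = _random_sample(rng, n=12)
    gene_set = set(rng.choice(expr.index, size=4, replace=False))
    s1 = ssgsea_score(expr, gene_set, weight_exponent=0.0)
    s2 = ssgsea_score(np.exp(expr * 3.0) + 7.0, gene_set, weight_exponent=0.0)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_degenerate_sets_error():
    expr = _random_sample(np.random.default_rng(0))
    with pytest.raises(ValueError, match="zero overlap"):
        ssgsea_score(expr, {"absent"})
    with pytest.raises(ValueError, match="entire universe"):
        ssgsea_score(expr, set(expr.index))


def test_matrix_drops_small_pathways_and_identical_samples_match(small_cohort):
    from pathdrp.io_formats import ExpressionMatrix, GeneSetCollection

    m = small_cohort.cells
    coll = GeneSetCollection(
        {"big": set(m.gene_ids[:20]), "tiny": set(m.gene_ids[:2])}
    )
    scored = ssgsea_matrix(m, coll, min_overlap=5)
    assert scored.pathway_names == ["big"]

    same = ExpressionMatrix(
        np.tile(m.values[:, :1], (1, 3)), m.gene_ids, ["a", "b", "c"],
        ["x"] * 3, ["NA"] * 3,
    )
    s = ssgsea_matrix(same, coll, min_overlap=5)
    assert s.scores.nunique().max() == 1  # identical samples, identical rows


def test_empty_collection_errors(small_cohort):
    from pathdrp.io_formats import GeneSetCollection

    with pytest.raises(ValueError, match="empty"):
        ssgsea_matrix(small_cohort.cells, GeneSetCollection({}))


def test_scores_track_planted_pathway_activity():
    cfg = SimulationConfig(
        n_genes=150, n_pathways=10, pathway_size_range=(10, 16),
        n_cell_samples=200, n_tumor_samples=20, n_drugs=2,
        noise_sd=0.5, seed=21,
    )
    c = generate_cohort(cfg)
    joint = harmonize_run([c.cells, c.tumors])
    scored = ssgsea_matrix(joint, c.pathways)
    act = pd.concat([c.truth.cell_activities, c.truth.tumor_activities])
    rs = [
        np.corrcoef(scored.scores[p], act.loc[scored.sample_ids, p])[0, 1]
        for p in scored.pathway_names
    ]
    assert np.mean(rs) > 0.5


def test_permutation_p_extreme_set_and_determinism():
    rng = np.random.default_rng(2)
    n = 40
    genes = [f"G{i}" for i in range(n)]
    vals = rng.normal(size=(n, 3))
    from pathdrp.io_formats import ExpressionMatrix, GeneSetCollection

    m = ExpressionMatrix(vals, genes, ["a", "b", "c"], ["x"] * 3, ["NA"] * 3)
    # per-sample top-5 genes cannot be beaten by any permutation
    top5 = {g for j in range(3) for g in np.array(genes)[np.argsort(-vals[:, j])[:5]]}
    coll = GeneSetCollection({"rand": set(genes[:8])})
    p1 = permutation_significance(m, coll, n_perm=200, seed=4)
    p2 = permutation_significance(m, coll, n_perm=200, seed=4)
    pd.testing.assert_frame_equal(p1, p2)
    # a sample's own top-ranked set achieves the minimal possible p
    single = ExpressionMatrix(vals[:, :1], genes, ["a"], ["x"], ["NA"])
    top_set = set(np.array(genes)[np.argsort(-vals[:, 0])[:5]])
    coll_top = GeneSetCollection({"top": top_set})
    p_top = permutation_significance(single, coll_top, n_perm=1000, seed=0)
    assert p_top.iloc[0, 0] == pytest.approx(1.0 / 1001.0)


def test_permutation_p_uniform_under_null():
    """On exchangeable data, permutation p-values are uniform on their grid."""
    from scipy.stats import kstest

    from pathdrp.io_formats import ExpressionMatrix, GeneSetCollection

    rng = np.random.default_rng(12)
    n = 30
    genes = [f"G{i}" for i in range(n)]
    m = ExpressionMatrix(
        rng.normal(size=(n, 60)), genes, [f"s{j}" for j in range(60)],
        ["x"] * 60, ["NA"] * 60,
    )
    coll = GeneSetCollection({"rand": set(rng.choice(genes, size=6, replace=False))})
    p = permutation_significance(m, coll, n_perm=200, seed=3)
    assert kstest(p.to_numpy().ravel(), "uniform").pvalue > 0.01


def test_n_perm_floor():
    from pathdrp.io_formats import ExpressionMatrix, GeneSetCollection

    m = ExpressionMatrix(np.random.default_rng(0).normal(size=(10, 2)),
                         [f"G{i}" for i in range(10)], ["a", "b"], ["x"] * 2, ["NA"] * 2)
    with pytest.raises(ValueError, match=">= 100"):
        permutation_significance(m, GeneSetCollection({"s": {"G1", "G2", "G3", "G4", "G5"}}), n_perm=50)
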