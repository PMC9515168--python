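"""Harmonization: gene intersection, standardization, empirical-Bayes batch
adjustment (with a hand-computed toy oracle and an independent reference
implementation cross-check)."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pathdrp.datagen import SimulationConfig, generate_cohort
from pathdrp.harmonize import (
    apply_combat,
    concat_samples,
    fit_combat,
    harmonize_run,
    intersect_genes,
    standardize_genewise,
)
from pathdrp.io_formats import ExpressionMatrix


def _em(values, genes, samples, batch):
    return ExpressionMatrix(values, genes, samples, batch, ["NA"] * len(samples))


def test_intersect_genes_sorted_common_set():
    a = _em(np.arange(6).reshape(3, 2), ["A", "B", "C"], ["s1", "s2"], ["x", "x"])
    b = _em(np.arange(6).reshape(3, 2), ["B", "C", "D"], ["t1", "t2"], ["y", "y"])
    out_a, out_b = intersect_genes([a, b])
    assert out_a.gene_ids == out_b.gene_ids == ["B", "C"]
    np.testing.assert_array_equal(out_a.values, a.values[[1, 2]])


def test_intersect_disjoint_errors():
    a = _em(np.ones((1, 2)), ["A"], ["s1", "s2"], ["x", "x"])
    b = _em(np.ones((1, 2)), ["B"], ["t1", "t2"], ["y", "y"])
    with pytest.raises(ValueError, match="empty gene intersection"):
        intersect_genes([a, b])


def test_standardize_genewise_moments_and_constant_drop():
    m = _em(
        np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
        ["G1", "G2"],
        ["s1", "s2", "s3"],
        ["b"] * 3,
    )
    out, stats = standardize_genewise(m)
    assert out.gene_ids == ["G1"]  # constant row dropped
    np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0], atol=1e-10)
    assert stats.loc["G1", "sd"] == pytest.approx(1.0)
    # idempotence: standardizing a standardized row leaves it unchanged
    again, _ = standardize_genewise(out)
    np.testing.assert_allclose(again.values, out.values, atol=1e-10)


def test_fit_combat_requires_multiple_batches_with_replicates():
    m = _em(np.random.default_rng(0).normal(size=(4, 6)), [f"G{i}" for i in range(4)],
            [f"s{i}" for i in range(6)], ["a"] * 6)
    with pytest.raises(ValueError, match=">= 2 batches"):
        fit_combat(m)
    m2 = _em(m.values, m.gene_ids, m.sample_ids, ["a"] * 5 + ["b"])
    with pytest.raises(ValueError, match="single sample"):
        fit_combat(m2)


def test_combat_toy_matches_hand_computation():
    """2-batch, 4-sample, single-gene toy: the hyperprior is degenerate so
    the adjustment reduces to per-batch location/scale removal, which we
    compute by hand."""
    vals = np.array([[1.0, 3.0, 10.0, 14.0]])
    m = _em(vals, ["G1"], ["s1", "s2", "s3", "s4"], ["a", "a", "b", "b"])
    std, stats = standardize_genewise(m)
    model = fit_combat(std, gene_stats=stats)
    out = apply_combat(std, model)

    z = (vals[0] - vals[0].mean()) / vals[0].std(ddof=1)
    expected = np.empty(4)
    for idx, sl in ((np.array([0, 1]), "a"), (np.array([2, 3]), "b")):
        zb = z[idx]
        expected[idx] = (zb - zb.mean()) / zb.std(ddof=1)
    expected = expected * vals[0].std(ddof=1) + vals[0].mean()
    np.testing.assert_allclose(out.values[0], expected, atol=1e-8)


def test_combat_recovers_planted_shift():
    """A +2 shift planted on one batch is estimated within 10% (on the
    standardized scale, the shift appears as +-1 around the pooled mean)."""
    rng = np.random.default_rng(42)
    n = 500
    base = rng.normal(0.0, 1.0, size=(50, 2 * n))
    base[:, n:] += 2.0
    m = _em(base, [f"G{i}" for i in range(50)], [f"s{i}" for i in range(2 * n)],
            ["a"] * n + ["b"] * n)
    std, stats = standardize_genewise(m)
    model = fit_combat(std, gene_stats=stats)
    gap = model.gamma_star[1] - model.gamma_star[0]
    # standardization divides by pooled sd ~ sqrt(1 + 1) so the gap is ~2/sqrt(2)
    expected = 2.0 / np.sqrt(2.0)
    assert np.abs(gap.mean() - expected) < 0.1 * expected


def test_combat_zero_effect_is_near_identity():
    rng = np.random.default_rng(7)
    n = 500
    vals = rng.normal(5.0, 1.0, size=(40, 2 * n))
    m = _em(vals, [f"G{i}" for i in range(40)], [f"s{i}" for i in range(2 * n)],
            ["a"] * n + ["b"] * n)
    std, stats = standardize_genewise(m)
    model = fit_combat(std, gene_stats=stats)
    assert np.abs(model.gamma_star).mean() < 0.1
    assert np.abs(model.delta_star - 1.0).mean() < 0.15
    out = apply_combat(std, model)
    orig = std.values * stats["sd"].to_numpy()[:, None] + stats["mean"].to_numpy()[:, None]
    assert np.abs(out.values - orig).max() < 0.05 * 5


def test_apply_combat_unknown_batch_errors():
    rng = np.random.default_rng(1)
    m = _em(rng.normal(size=(5, 8)), [f"G{i}" for i in range(5)],
            [f"s{i}" for i in range(8)], ["a"] * 4 + ["b"] * 4)
    std, stats = standardize_genewise(m)
    model = fit_combat(std, gene_stats=stats)
    alien = _em(std.values, std.gene_ids, std.sample_ids, ["c"] * 8)
    with pytest.raises(ValueError, match="unknown batch"):
        apply_combat(alien, model)


def test_harmonize_run_equalizes_batch_means():
    cfg = SimulationConfig(
        n_genes=80, n_pathways=8, pathway_size_range=(6, 10),
        n_cell_samples=300, n_tumor_samples=100, n_drugs=2,
        batch_shift_sd=2.0, batch_scale_range=(0.5, 2.0), seed=13,
    )
    c = generate_cohort(cfg)
    joint = harmonize_run([c.cells, c.tumors])
    arr = np.array(joint.batch)
    batches = sorted(set(joint.batch))
    means = {b: joint.values[:, arr == b].mean(axis=1) for b in batches}
    ses = {
        b: joint.values[:, arr == b].std(axis=1, ddof=1) / np.sqrt((arr == b).sum())
        for b in batches
    }
    # >= 95% of genes within 3 standard errors of equal batch means
    ok = 0
    total = 0
    for i, a in enumerate(batches):
        for b in batches[i + 1 :]:
            se = np.sqrt(ses[a] ** 2 + ses[b] ** 2)
            ok += (np.abs(means[a] - means[b]) < 3 * se).sum()
            total += joint.n_genes
    assert ok / total >= 0.95


def test_harmonize_run_approximately_idempotent():
    rng = np.random.default_rng(3)
    n = 200
    vals = rng.normal(0.0, 1.0, size=(30, 2 * n))
    a = _em(vals[:, :n], [f"G{i}" for i in range(30)], [f"s{i}" for i in range(n)], ["a"] * n)
    b = _em(vals[:, n:], [f"G{i}" for i in range(30)], [f"t{i}" for i in range(n)], ["b"] * n)
    once = harmonize_run([a, b])
    arr = np.array(once.batch)
    a2 = _em(once.values[:, arr == "a"], once.gene_ids,
             [s for s, k in zip(once.sample_ids, arr == "a") if k], ["a"] * n)
    b2 = _em(once.values[:, arr == "b"], once.gene_ids,
             [s for s, k in zip(once.sample_ids, arr == "b") if k], ["b"] * n)
    twice = harmonize_run([a2, b2])
    # zero planted effect: the second pass only re-standardizes
    resid = np.abs(twice.values - once.values)
    assert np.median(resid) < 0.05


def test_combat_agrees_with_reference_implementation(tmp_path):
    """Cross-check against the Bioconductor reference (sva::ComBat). The two
    formulations standardize slightly differently, so we require strong
    agreement (r > 0.95) and that both equalize batch means, not equality."""
    rng = np.random.default_rng(11)
    n = 30
    vals = rng.normal(0.0, 1.0, size=(40, 2 * n))
    vals[:, n:] += rng.normal(1.0, 0.5, size=(40, 1))
    genes = [f"G{i}" for i in range(40)]
    samples = [f"s{i}" for i in range(2 * n)]
    m = _em(vals, genes, samples, ["a"] * n + ["b"] * n)
    std, stats = standardize_genewise(m)
    ours = apply_combat(std, fit_combat(std, gene_stats=stats))

    expr_path = tmp_path / "expr.tsv"
    pd.DataFrame(vals, index=genes, columns=samples).to_csv(expr_path, sep="\t")
    out_path = tmp_path / "combat.tsv"
    script = textwrap.dedent(f"""
        suppressMessages(library(sva))
        x <- as.matrix(read.delim("{expr_path}", row.names = 1))
        batch <- c(rep("a", {n}), rep("b", {n}))
        y <- ComBat(dat = x, batch = batch)
        write.table(y, "{out_path}", sep = "\\t", quote = FALSE)
    """)
    r_script = tmp_path / "combat.R"
    r_script.write_text(script)
    res = subprocess.run(
        ["Rscript", "--vanilla", str(r_script)], capture_output=True, text=True
    )
    assert res.returncode == 0, res.stderr
    ref = pd.read_csv(out_path, sep="\t", index_col=0).to_numpy()

    r = np.corrcoef(ours.values.ravel(), ref.ravel())[0, 1]
    assert r > 0.95
    for adj in (ours.values, ref):
        gap = np.abs(adj[:, :n].mean(axis=1) - adj[:, n:].mean(axis=1)).mean()
        assert gap < 0.15
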