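"""Layer transfer, freeze contract, imbalance subsampling, and the
sequential model-based hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

from pathdrp.io_formats import ResponseTable
from pathdrp.model_core import FeatureTable, TrainConfig, build_network, predict, pretrain
from pathdrp.transfer import (
    TransferConfig,
    fine_tune,
    hyperparameter_search,
    subsample_nonresponders,
    transfer_build,
)


@pytest.fixture(scope="module")
def source_model():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 6))
    y = np.clip(X @ rng.normal(size=6) * 0.15 + 0.5, 0, 1)
    table = FeatureTable(X, y, [f"s{i}" for i in range(200)], ["d0"] * 200,
                         [f"f{j}" for j in range(6)], {})
    return pretrain(table, TrainConfig(max_epochs=30, seed=0, learning_rate=0.01),
                    widths=(10, 6, 4))


def _clf_table(rng, n=120):
    X = rng.normal(size=(n, 6))
    w = rng.normal(size=6)
    y = (X @ w > 0).astype(float)
    return FeatureTable(X, y, [f"s{i}" for i in range(n)], ["d0"] * n,
                        [f"f{j}" for j in range(6)], {})


def test_transfer_build_copies_and_flags_layers(source_model):
    cfg = TransferConfig(n_transfer_layers=2, retrain_transferred=False,
                         head="classification", seed=5)
    m = transfer_build(source_model, cfg)
    for i in range(2):
        np.testing.assert_array_equal(m.weights[i], source_model.weights[i])
        assert m.pretrained_flags[i] and m.frozen_flags[i]
    assert not m.pretrained_flags[2]
    assert m.head == "classification"
    assert m.widths == [10, 6]


def test_transfer_zero_layers_is_fresh(source_model):
    cfg = TransferConfig(n_transfer_layers=0, new_hidden_layers=(10, 6, 4),
                         head="classification", seed=5)
    m = transfer_build(source_model, cfg)
    assert not any(m.pretrained_flags)
    assert any(
        not np.array_equal(w, sw) for w, sw in zip(m.weights, source_model.weights)
    )


def test_transfer_too_many_layers_errors(source_model):
    with pytest.raises(ValueError, match="cannot transfer"):
        transfer_build(source_model, TransferConfig(n_transfer_layers=5))


def test_freeze_contract_is_bitwise(source_model, rng):
    table = _clf_table(rng)
    cfg = TransferConfig(
        n_transfer_layers=3, retrain_transferred=False, head="classification",
        train=TrainConfig(loss="bce", max_epochs=30, learning_rate=0.01, seed=2),
        seed=2,
    )
    m = transfer_build(source_model, cfg)
    before = [w.copy() for w in m.weights[:3]]
    tuned = fine_tune(m, table, cfg)
    for w0, w1 in zip(before, tuned.weights[:3]):
        assert np.array_equal(w0, w1)  # bitwise
    # the head must have moved
    assert not np.array_equal(m.weights[-1], tuned.weights[-1])


def test_fine_tune_regression_noiseless(rng):
    X = rng.normal(size=(200, 6))
    y = np.clip(X @ rng.normal(size=6) * 0.1 + 0.5, 0, 1)
    table = FeatureTable(X, y, [f"s{i}" for i in range(200)], ["d0"] * 200,
                         [f"f{j}" for j in range(6)], {})
    source = pretrain(table, TrainConfig(max_epochs=30, seed=0, learning_rate=0.01),
                      widths=(10, 6))
    cfg = TransferConfig(
        n_transfer_layers=2, retrain_transferred=True, head="regression",
        train=TrainConfig(loss="mse", max_epochs=150, patience=30,
                          learning_rate=0.01, dropout=0.0, seed=1),
        seed=1,
    )
    tuned = fine_tune(transfer_build(source, cfg), table, cfg)
    best = [e for e in tuned.training_log if "best_val_loss" in e][-1]
    assert np.sqrt(best["best_val_loss"]) < 0.05  # MSE -> RMSE


def test_head_response_kind_mismatch(source_model, rng):
    X = rng.normal(size=(30, 6))
    table = FeatureTable(X, rng.uniform(0.1, 0.9, size=30), [f"s{i}" for i in range(30)],
                         ["d0"] * 30, [f"f{j}" for j in range(6)], {})
    cfg = TransferConfig(n_transfer_layers=3, head="classification", seed=0)
    with pytest.raises(ValueError, match="dichotomous"):
        fine_tune(transfer_build(source_model, cfg), table, cfg)


def _dich_table(counts):
    rows = []
    for drug, (n_resp, n_non) in counts.items():
        for i in range(n_resp):
            rows.append((f"{drug}r{i}", drug, 1.0))
        for i in range(n_non):
            rows.append((f"{drug}n{i}", drug, 0.0))
    return ResponseTable(pd.DataFrame(rows, columns=["sample_id", "drug_id", "outcome"]),
                         "dichotomous")


def test_subsample_reaches_one_to_three():
    out = subsample_nonresponders(_dich_table({"d1": (5, 40)}), ratio=3, seed=0)
    assert (out.frame["outcome"] == 1.0).sum() == 5
    assert (out.frame["outcome"] == 0.0).sum() == 15


def test_subsample_caps_at_available_nonresponders():
    out = subsample_nonresponders(_dich_table({"d1": (5, 10)}), ratio=3, seed=0)
    assert (out.frame["outcome"] == 0.0).sum() == 10
    assert (out.frame["outcome"] == 1.0).sum() == 5


def test_subsample_never_removes_responders_never_duplicates():
    table = _dich_table({"d1": (7, 50), "d2": (3, 4)})
    out = subsample_nonresponders(table, ratio=3, seed=5)
    resp_in = set(table.frame.query("outcome == 1")["sample_id"])
    resp_out = set(out.frame.query("outcome == 1")["sample_id"])
    assert resp_in == resp_out
    assert not out.frame.duplicated(["sample_id", "drug_id"]).any()


def test_subsample_drops_zero_responder_drug_and_rejects_bad_ratio():
    out = subsample_nonresponders(_dich_table({"d1": (0, 10), "d2": (2, 9)}), ratio=3)
    assert set(out.frame["drug_id"]) == {"d2"}
    with pytest.raises(ValueError):
        subsample_nonresponders(_dich_table({"d1": (2, 9)}), ratio=0)


def test_search_budget_one_returns_single_point():
    space = {"lr": [0.1, 0.2, 0.3]}
    best, trace = hyperparameter_search(lambda p: p["lr"], space, budget=1, seed=0)
    assert len(trace) == 1
    assert best == trace[0]["params"]


def test_search_finds_unimodal_optimum_in_top_decile():
    grid = list(np.linspace(0.001, 1.0, 50))
    space = {"lr": grid, "depth": [1, 2]}

    def objective(p):
        return (np.log10(p["lr"]) - np.log10(0.05)) ** 2 + 0.1 * (p["depth"] - 1)

    best, trace = hyperparameter_search(objective, space, budget=20, seed=1)
    values = sorted(objective({"lr": g, "depth": d}) for g in grid for d in (1, 2))
    top_decile = values[len(values) // 10]
    assert objective(best) <= top_decile
    assert len(trace) == 20


def test_search_is_deterministic():
    space = {"a": [1, 2, 3, 4, 5], "b": [0.1, 0.2, 0.3]}
    obj = lambda p: p["a"] * p["b"]
    _, t1 = hyperparameter_search(obj, space, budget=8, seed=3)
    _, t2 = hyperparameter_search(obj, space, budget=8, seed=3)
    assert t1 == t2


def test_search_empty_space_errors():
    with pytest.raises(ValueError):
        hyperparameter_search(lambda p: 0.0, {}, budget=5)
    with pytest.raises(ValueError):
        hyperparameter_search(lambda p: 0.0, {"a": []}, budget=5)
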