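"""Transfer of the pre-trained cell-line network to a tumor/PDX task.

A configurable number of the pre-trained hidden layers initialize the
target network (optionally frozen); any new hidden layers and the task head
are freshly seeded. Fine-tuning uses binary cross-entropy for dichotomous
responders and MSE for continuous sensitivity, with the same early-stopping
and weight-clipping discipline as pre-training. Heavily imbalanced
dichotomous panels are rebalanced per drug by subsampling non-responders to
a fixed responder:non-responder ratio (default 1:3). Hyperparameters are
searched with a sequential model-based (Gaussian-process expected-
improvement) optimizer over a finite grid.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from scipy.stats import norm

from pathdrp.io_formats import ResponseTable
from pathdrp.model_core import (
    FeatureTable,
    SensitivityModel,
    TrainConfig,
    build_network,
    train_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TransferConfig",
    "transfer_build",
    "subsample_nonresponders",
    "fine_tune",
    "hyperparameter_search",
]


@dataclasses.dataclass
class TransferConfig:
    n_transfer_layers: int = 4
    retrain_transferred: bool = True
    new_hidden_layers: tuple[int, ...] = ()
    head: str = "classification"
    train: TrainConfig = dataclasses.field(
        default_factory=lambda: TrainConfig(loss="bce")
    )
    subsample_ratio: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transfer_layers < 0:
            raise ValueError("n_transfer_layers must be >= 0")
        if self.subsample_ratio < 1:
            raise ValueError("subsample ratio denominator must be >= 1")


def transfer_build(pretrained: SensitivityModel, cfg: TransferConfig) -> SensitivityModel:
    """Target network: first ``n_transfer_layers`` hidden layers copied from
    the pre-trained model (frozen unless ``retrain_transferred``), new
    hidden layers and the task head freshly initialized."""
    n_hidden = len(pretrained.widths)
    if cfg.n_transfer_layers > n_hidden:
        raise ValueError(
            f"cannot transfer {cfg.n_transfer_layers} layers from a "
            f"{n_hidden}-hidden-layer source"
        )
    kept = pretrained.widths[: cfg.n_transfer_layers]
    widths = list(kept) + list(cfg.new_hidden_layers)
    if not widths:
        widths = []  # direct input -> head
    model = build_network(
        pretrained.input_dim,
        cfg.head,
        tuple(widths) if widths else (),
        dropout=cfg.train.dropout,
        activation=pretrained.activation,
        seed=cfg.seed,
    )
    for i in range(cfg.n_transfer_layers):
        model.weights[i] = pretrained.weights[i].copy()
        model.biases[i] = pretrained.biases[i].copy()
        model.pretrained_flags[i] = True
        model.frozen_flags[i] = not cfg.retrain_transferred
    return model


def subsample_nonresponders(
    table: ResponseTable, ratio: int = 3, seed: int = 0
) -> ResponseTable:
    """Per drug: keep every responder, sample non-responders without
    replacement down to ``ratio`` times the responders (or all, if fewer).
    Drugs with zero responders are dropped with a warning."""
    if table.outcome_kind != "dichotomous":
        raise ValueError("subsampling requires a dichotomous table")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    kept = []
    for drug, sub in table.frame.groupby("drug_id", sort=True):
        resp = sub[sub["outcome"] == 1.0]
        nonresp = sub[sub["outcome"] == 0.0]
        if len(resp) == 0:
            logger.warning("drug %r has no responders; dropped", drug)
            continue
        n_keep = min(len(nonresp), ratio * len(resp))
        idx = rng.choice(nonresp.index.to_numpy(), size=n_keep, replace=False)
        kept.append(resp)
        kept.append(nonresp.loc[np.sort(idx)])
    if not kept:
        raise ValueError("no drug with responders; nothing to subsample")
    out = pd.concat(kept).sort_values(["drug_id", "sample_id"]).reset_index(drop=True)
    return ResponseTable(out, "dichotomous")


def fine_tune(
    model: SensitivityModel, table: FeatureTable, cfg: TransferConfig
) -> SensitivityModel:
    """Fine-tune a transferred network on the target task; frozen layers are
    bitwise untouched and the training log records which layers updated."""
    dichotomous = bool(np.isin(table.y, [0.0, 1.0]).all())
    if model.head == "classification" and not dichotomous:
        raise ValueError("classification head requires dichotomous responses")
    tuned = train_model(model, table, cfg.train)
    tuned.training_log.append(
        {"updated_layers": [i for i, f in enumerate(tuned.frozen_flags) if not f]}
    )
    return tuned


# ---------------------------------------------------------------------------
# Sequential model-based hyperparameter search


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return sd * (z * norm.cdf(z) + norm.pdf(z))


def hyperparameter_search(
    objective,
    search_space: dict[str, list],
    budget: int,
    seed: int = 0,
    n_init: int = 5,
) -> tuple[dict, list[dict]]:
    """Minimize ``objective(params)`` over a finite grid by Gaussian-process
    expected improvement.

    ``search_space`` maps each dimension (e.g. learning_rate, batch_size,
    dropout, optimizer, activation, new-layer widths, n_transfer_layers,
    retrain flag) to its finite list of choices. Returns the best parameter
    dict and a trace of every evaluated point. Deterministic under ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space must list at least one choice per dimension")
    dims = sorted(search_space)
    grid = [dict(zip(dims, combo)) for combo in itertools.product(*(search_space[d] for d in dims))]
    # encode each dimension as its normalized choice index
    enc = np.array(
        [
            [search_space[d].index(pt[d]) / max(1, len(search_space[d]) - 1) for d in dims]
            for pt in grid
        ]
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(grid))
    evaluated: list[int] = []
    trace: list[dict] = []

    def run(i: int) -> None:
        val = float(objective(grid[i]))
        evaluated.append(i)
        trace.append({"params": grid[i], "objective": val})

    for i in order[: min(n_init, budget, len(grid))]:
        run(int(i))
    while len(trace) < min(budget, len(grid)):
        y = np.array([t["objective"] for t in trace])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-6, random_state=0
        )
        gp.fit(enc[evaluated], y)
        remaining = np.setdiff1d(np.arange(len(grid)), np.array(evaluated))
        mu, sd = gp.predict(enc[remaining], return_std=True)
        ei = _expected_improvement(mu, sd, y.min())
        run(int(remaining[int(np.argmax(ei))]))

    best = min(trace, key=lambda t: t["objective"])
    return best["params"], trace
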