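"""The feed-forward drug-sensitivity network and its trainer.

The reference architecture has four hidden layers (1000, 800, 500, 100
neurons), ELU activations, neuron-level dropout at 10%, and a task head:
a linear output for regression on continuous sensitivity (1-AUC of the
dose-response curve, or -log10 IC50) or a sigmoid output for responder
classification. Training uses the Adamax optimizer at learning rate 4e-4,
RMSE/MSE/BCE losses, weight values clipped to [-5, 5] after every gradient
update, and early stopping with patience on a held-out validation split
(10% of the training data, stratified by drug), restoring the
best-validation weights.

Everything is plain numpy with hand-written backpropagation: widths are
configurable down to toy scale, runs are CPU-only and bit-reproducible
from the seed, and per-layer provenance (pretrained / frozen) is tracked so
transfer learning can freeze transferred layers bitwise.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pathdrp.io_formats import ResponseTable

__all__ = [
    "TrainConfig",
    "SensitivityModel",
    "FeatureTable",
    "assemble_features",
    "build_network",
    "pretrain",
    "predict",
    "save_model",
    "load_model",
    "train_model",
]

_MODEL_VERSION = 1
DEFAULT_WIDTHS = (1000, 800, 500, 100)


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 0.0004
    patience: int = 30
    dropout: float = 0.10
    clip_range: tuple[float, float] = (-5.0, 5.0)
    optimizer: str = "adamax"
    loss: str = "rmse"
    batch_size: int = 128
    max_epochs: int = 300
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        lo, hi = self.clip_range
        if lo >= hi:
            raise ValueError("clip_range bounds must be ordered")
        if self.loss not in ("rmse", "mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adamax", "adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclasses.dataclass
class FeatureTable:
    """Per-(sample, drug) rows: EXP || CHEM || DGNet features + response."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    drug_ids: list[str]
    feature_names: list[str]
    blocks: dict[str, slice]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("feature/response row mismatch")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.X[idx],
            self.y[idx],
            [self.sample_ids[i] for i in idx],
            [self.drug_ids[i] for i in idx],
            self.feature_names,
            self.blocks,
        )


def assemble_features(exp_scores, chem: dict, dgnet: dict, response: ResponseTable) -> FeatureTable:
    """Concatenate EXP || CHEM || DGNet per (sample, drug) row of a response
    table. ``exp_scores`` is a PathwayScoreMatrix; ``chem``/``dgnet`` map
    drug_id to ChemFingerprint / DGNetVector."""
    pw = exp_scores.pathway_names
    any_drug = next(iter(chem))
    n_chem = len(chem[any_drug].bits)
    dg_names = dgnet[any_drug].pathway_names
    names = (
        [f"EXP:{p}" for p in pw]
        + [f"CHEM:{i}" for i in range(n_chem)]
        + [f"DGNET:{p}" for p in dg_names]
    )
    blocks = {
        "EXP": slice(0, len(pw)),
        "CHEM": slice(len(pw), len(pw) + n_chem),
        "DGNET": slice(len(pw) + n_chem, len(names)),
    }
    exp = exp_scores.scores
    rows = np.empty((len(response.frame), len(names)))
    for i, (_, rec) in enumerate(response.frame.iterrows()):
        s, d = rec["sample_id"], rec["drug_id"]
        rows[i] = np.concatenate(
            [exp.loc[s].to_numpy(), chem[d].bits.astype(float), dgnet[d].scores]
        )
    return FeatureTable(
        rows,
        response.frame["outcome"].to_numpy(dtype=float),
        response.frame["sample_id"].tolist(),
        response.frame["drug_id"].tolist(),
        names,
        blocks,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    df.insert(1, "drug_id", table.drug_ids)
    df.insert(2, "outcome", table.y)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug_id": str})
    feat_cols = [c for c in df.columns if c not in ("sample_id", "drug_id", "outcome")]
    blocks: dict[str, slice] = {}
    for prefix in ("EXP", "CHEM", "DGNET"):
        idx = [i for i, c in enumerate(feat_cols) if c.startswith(prefix + ":")]
        if idx:
            blocks[prefix] = slice(min(idx), max(idx) + 1)
    return FeatureTable(
        df[feat_cols].to_numpy(dtype=float),
        df["outcome"].to_numpy(dtype=float),
        df["sample_id"].tolist(),
        df["drug_id"].tolist(),
        feat_cols,
        blocks,
    )


@dataclasses.dataclass
class SensitivityModel:
    """Layered feed-forward network with per-layer provenance metadata."""

    input_dim: int
    widths: list[int]
    head: str  # "regression" | "classification"
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "elu"
    dropout: float = 0.10
    pretrained_flags: list[bool] = dataclasses.field(default_factory=list)
    frozen_flags: list[bool] = dataclasses.field(default_factory=list)
    training_log: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        n_layers = len(self.widths) + 1
        if len(self.weights) != n_layers or len(self.biases) != n_layers:
            raise ValueError("weights/biases do not match the declared widths")
        if not self.pretrained_flags:
            self.pretrained_flags = [False] * n_layers
        if not self.frozen_flags:
            self.frozen_flags = [False] * n_layers

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "SensitivityModel":
        return copy.deepcopy(self)


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(z > 0, z, np.expm1(z))
    if kind == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(z > 0, 1.0, a + 1.0)
    if kind == "relu":
        return (z > 0).astype(float)
    raise ValueError(f"unknown activation {kind!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(
    input_dim: int,
    head: str,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
    dropout: float = 0.10,
    activation: str = "elu",
    seed: int = 0,
) -> SensitivityModel:
    """Fresh network with seeded uniform fan-in initialization."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    widths = list(widths)
    if any(w <= 0 for w in widths):
        raise ValueError("layer widths must be positive")
    if head not in ("regression", "classification"):
        raise ValueError(f"unknown head {head!r}")
    rng = np.random.default_rng(seed)
    dims = [input_dim] + widths + [1]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(d_in)
        weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
        biases.append(rng.uniform(-bound, bound, size=d_out))
    return SensitivityModel(
        input_dim, widths, head, weights, biases, activation=activation, dropout=dropout
    )


def _forward(
    model: SensitivityModel,
    X: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list]:
    """Forward pass; returns (output, cache). Dropout only when training."""
    cache = []
    h = X
    n_hidden = len(model.widths)
    for i in range(n_hidden):
        z = h @ model.weights[i] + model.biases[i]
        a = _activate(z, model.activation)
        mask = None
        if train and model.dropout > 0:
            mask = (rng.random(a.shape) >= model.dropout) / (1.0 - model.dropout)
            a = a * mask
        cache.append((h, z, a, mask))
        h = a
    z_out = h @ model.weights[-1] + model.biases[-1]
    if model.head == "classification":
        out = _sigmoid(z_out)
    else:
        out = z_out
    cache.append((h, z_out, out, None))
    return out[:, 0], cache


def _loss_value(y: np.ndarray, pred: np.ndarray, loss: str) -> float:
    if loss == "mse":
        return float(np.mean((pred - y) ** 2))
    if loss == "rmse":
        return float(np.sqrt(np.mean((pred - y) ** 2)))
    if loss == "bce":
        p = np.clip(pred, 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    raise ValueError(loss)


def _output_grad(y: np.ndarray, pred: np.ndarray, z_out: np.ndarray, loss: str, head: str) -> np.ndarray:
    """dL/dz at the output pre-activation, shape (n, 1)."""
    n = len(y)
    if head == "classification":
        if loss != "bce":
            raise ValueError("classification head requires BCE loss")
        g = (pred - y) / n
    else:
        if loss == "mse":
            g = 2.0 * (pred - y) / n
        elif loss == "rmse":
            r = float(np.sqrt(np.mean((pred - y) ** 2)))
            g = (pred - y) / (n * max(r, 1e-12))
        else:
            raise ValueError("regression head requires MSE or RMSE loss")
    return g[:, None]


class _Optimizer:
    """Adamax / Adam / SGD over the model's parameter list."""

    def __init__(self, model: SensitivityModel, cfg: TrainConfig):
        self.kind = cfg.optimizer
        self.lr = cfg.learning_rate
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        params = model.weights + model.biases
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if g is None:
                continue
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "adamax":
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.u[i] = np.maximum(self.beta2 * self.u[i], np.abs(g))
                p -= (self.lr / (1 - self.beta1**self.t)) * self.m[i] / (self.u[i] + self.eps)
            else:  # adam
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.u[i] = self.beta2 * self.u[i] + (1 - self.beta2) * g**2
                m_hat = self.m[i] / (1 - self.beta1**self.t)
                u_hat = self.u[i] / (1 - self.beta2**self.t)
                p -= self.lr * m_hat / (np.sqrt(u_hat) + self.eps)


def _backward(
    model: SensitivityModel, cache: list, dz_out: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    n_layers = model.n_layers
    gw = [None] * n_layers
    gb = [None] * n_layers
    h_last, _, _, _ = cache[-1]
    gw[-1] = h_last.T @ dz_out
    gb[-1] = dz_out.sum(axis=0)
    delta = dz_out @ model.weights[-1].T
    for i in range(n_layers - 2, -1, -1):
        h_in, z, a, mask = cache[i]
        if mask is not None:
            delta = delta * mask
        # a here includes the dropout scaling; recompute pre-dropout activation grad
        a_raw = a if mask is None else a / np.where(mask == 0, 1.0, mask)
        delta = delta * _activate_grad(z, a_raw, model.activation)
        gw[i] = h_in.T @ delta
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ model.weights[i].T
    return gw, gb


def _val_split(
    table: FeatureTable, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out validation indices, stratified by drug (and label when the
    responses are dichotomous)."""
    n = table.n_rows
    dichotomous = np.isin(table.y, [0.0, 1.0]).all()
    keys = [
        (d, table.y[i]) if dichotomous else (d,)
        for i, d in enumerate(table.drug_ids)
    ]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    val: list[int] = []
    for k in sorted(groups):
        idx = np.array(groups[k])
        n_val = max(1, int(round(cfg.val_fraction * len(idx)))) if len(idx) > 1 else 0
        chosen = rng.choice(idx, size=n_val, replace=False)
        val.extend(chosen.tolist())
    val_idx = np.array(sorted(val), dtype=int)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if len(val_idx) == 0:
        raise ValueError("empty validation split; not enough rows per stratum")
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    return train_idx, val_idx


def train_model(
    model: SensitivityModel, table: FeatureTable, cfg: TrainConfig
) -> SensitivityModel:
    """Mini-batch training with early stopping; frozen layers are never
    updated and post-update weight clipping keeps every trainable weight in
    ``cfg.clip_range`` at all times. Returns the model with best-validation
    weights restored and an epoch-by-epoch training log."""
    if table.n_rows < 2:
        raise ValueError("need at least 2 rows to train")
    if model.head == "classification" and cfg.loss != "bce":
        raise ValueError("classification head requires BCE loss")
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _val_split(table, cfg, rng)
    X_tr, y_tr = table.X[train_idx], table.y[train_idx]
    X_val, y_val = table.X[val_idx], table.y[val_idx]

    model = model.copy()
    model.training_log = []
    opt = _Optimizer(model, cfg)
    lo, hi = cfg.clip_range
    best_val = np.inf
    best_state = None
    best_epoch = -1
    wait = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred, cache = _forward(model, X_tr[idx], train=True, rng=rng)
            dz = _output_grad(y_tr[idx], pred, cache[-1][1], cfg.loss, model.head)
            gw, gb = _backward(model, cache, dz)
            for i in range(model.n_layers):
                if model.frozen_flags[i]:
                    gw[i] = None
                    gb[i] = None
            opt.step(model.weights + model.biases, gw + gb)
            for i in range(model.n_layers):
                if not model.frozen_flags[i]:
                    np.clip(model.weights[i], lo, hi, out=model.weights[i])
                    np.clip(model.biases[i], lo, hi, out=model.biases[i])
        train_loss = _loss_value(y_tr, _forward(model, X_tr)[0], cfg.loss)
        val_loss = _loss_value(y_val, _forward(model, X_val)[0], cfg.loss)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        model.training_log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = (
                [w.copy() for w in model.weights],
                [b.copy() for b in model.biases],
            )
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    if best_state is not None:
        model.weights = best_state[0]
        model.biases = best_state[1]
    model.training_log.append({"best_epoch": best_epoch, "best_val_loss": best_val})
    return model


def pretrain(
    table: FeatureTable,
    config: TrainConfig | None = None,
    widths: tuple[int, ...] = DEFAULT_WIDTHS,
) -> SensitivityModel:
    """Train the cell-line sensitivity regressor from scratch on continuous
    sensitivity (1-AUC or -log10 IC50) with the RMSE loss."""
    cfg = config or TrainConfig()
    if not np.all(np.isfinite(table.y)):
        raise ValueError("target column contains non-finite values")
    model = build_network(
        table.n_features, "regression", widths, dropout=cfg.dropout, seed=cfg.seed
    )
    return train_model(model, table, cfg)


def predict(model: SensitivityModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout disabled); probabilities for the
    classification head."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model input {model.input_dim}"
        )
    return _forward(model, X, train=False)[0]


def save_model(model: SensitivityModel, path: str | Path) -> None:
    """Versioned archive: JSON metadata plus the weight arrays."""
    meta = {
        "version": _MODEL_VERSION,
        "input_dim": model.input_dim,
        "widths": model.widths,
        "head": model.head,
        "activation": model.activation,
        "dropout": model.dropout,
        "pretrained_flags": model.pretrained_flags,
        "frozen_flags": model.frozen_flags,
        "training_log": model.training_log,
    }
    arrays = {f"W{i}": w for i, w in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> SensitivityModel:
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            n_layers = len(meta["widths"]) + 1
            weights = [data[f"W{i}"] for i in range(n_layers)]
            biases = [data[f"b{i}"] for i in range(n_layers)]
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if meta.get("version") != _MODEL_VERSION:
        raise ValueError(
            f"model version {meta.get('version')} != supported {_MODEL_VERSION}"
        )
    return SensitivityModel(
        meta["input_dim"],
        meta["widths"],
        meta["head"],
        weights,
        biases,
        activation=meta["activation"],
        dropout=meta["dropout"],
        pretrained_flags=meta["pretrained_flags"],
        frozen_flags=meta["frozen_flags"],
        training_log=meta["training_log"],
    )
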