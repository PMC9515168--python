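"""Synthetic multi-batch cohorts with planted pathway-level response signal.

The generator emulates the statistical structure the pipeline assumes:

* pathways tile the gene universe (with overlap); each sample carries a
  latent activity a_p ~ N(0,1) per pathway, and member genes read
  baseline + a_p + N(0, noise_sd);
* each batch applies a gene-wise location/scale distortion (additive shift
  ~ N(0, batch_shift_sd), multiplicative scale ~ U(batch_scale_range)) —
  exactly the model empirical-Bayes batch adjustment removes;
* the PPI graph is dense within pathways and sparse across;
* each drug acts through a few signal pathways; its targets are drawn from
  those pathways; continuous sensitivity is a logistic function of the
  weighted latent activities plus noise, clipped to [0,1]; dichotomous
  labels split at the per-drug cohort median;
* cell-line and tumor samples share the same generative law (so transferring
  a cell-line model to the tumor task genuinely helps) but the tumor cohort
  is small.

A GroundTruth record (signal pathways, effect weights, latent activities)
is returned so downstream recovery can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from pathdrp.io_formats import (
    DrugRecord,
    ExpressionMatrix,
    GeneSetCollection,
    ResponseTable,
)

__all__ = ["SimulationConfig", "GroundTruth", "Cohort", "generate_cohort", "make_imbalanced"]

_SCAFFOLDS = [
    "CCO", "CCN", "CC(=O)O", "c1ccccc1", "CC(C)O", "CCOC", "CCS",
    "c1ccncc1", "CC(N)C(=O)O", "C1CCCCC1", "CC(=O)N", "COc1ccccc1",
]


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions."""

    n_genes: int = 200
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 20)
    n_cell_samples: int = 2000
    n_tumor_samples: int = 80
    n_batches: int = 2
    batch_shift_sd: float = 1.0
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    n_drugs: int = 5
    n_signal_pathways_per_drug: int = 3
    effect_size: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_genes, self.n_pathways, self.n_cell_samples,
            self.n_tumor_samples, self.n_batches, self.n_drugs,
            self.n_signal_pathways_per_drug,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.pathway_size_range
        if hi > self.n_genes:
            raise ValueError(
                f"pathway_size_range upper bound {hi} exceeds n_genes {self.n_genes}"
            )
        if lo < 1 or lo > hi:
            raise ValueError("invalid pathway_size_range")
        if self.n_signal_pathways_per_drug > self.n_pathways:
            raise ValueError("n_signal_pathways_per_drug exceeds n_pathways")


@dataclasses.dataclass
class GroundTruth:
    """Per-drug planted signal (pathway ids + signed weights) and per-sample
    latent pathway activities, split by cohort."""

    signal_pathways: dict[str, dict[str, float]]  # drug_id -> {pathway: weight}
    drug_intercepts: dict[str, float]
    cell_activities: pd.DataFrame  # samples x pathways
    tumor_activities: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signal_pathways": self.signal_pathways,
            "drug_intercepts": self.drug_intercepts,
            "cell_activities": self.cell_activities.to_dict(orient="split"),
            "tumor_activities": self.tumor_activities.to_dict(orient="split"),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


@dataclasses.dataclass
class Cohort:
    cells: ExpressionMatrix
    tumors: ExpressionMatrix
    pathways: GeneSetCollection
    drugs: list[DrugRecord]
    ppi: nx.Graph
    cell_response_continuous: ResponseTable
    tumor_response_dichotomous: ResponseTable
    tumor_response_continuous: ResponseTable
    truth: GroundTruth


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _make_pathways(cfg: SimulationConfig, rng: np.random.Generator) -> GeneSetCollection:
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.pathway_size_range
    sets: dict[str, set[str]] = {}
    # contiguous blocks with random jitter: every gene covered, neighbours overlap
    starts = np.linspace(0, cfg.n_genes, cfg.n_pathways, endpoint=False).astype(int)
    for p, start in enumerate(starts):
        size = int(rng.integers(lo, hi + 1))
        block = [genes[(start + j) % cfg.n_genes] for j in range(size)]
        extra = rng.choice(cfg.n_genes, size=max(1, size // 5), replace=False)
        sets[f"PW{p:03d}"] = set(block) | {genes[i] for i in extra}
    return GeneSetCollection(sets, provenance="SYNTHETIC")


def _expression_for(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pathways: GeneSetCollection,
    gene_index: dict[str, int],
    activities: np.ndarray,  # n_samples x n_pathways
    baseline: np.ndarray,  # n_genes
) -> np.ndarray:
    """genes x samples expression from latent pathway activities (no batch)."""
    n_samples = activities.shape[0]
    values = np.tile(baseline[:, None], (1, n_samples))
    # membership count so overlapping pathways average rather than stack
    membership = np.zeros((cfg.n_genes, len(pathways)), dtype=float)
    for p, name in enumerate(pathways.names):
        for g in pathways[name]:
            membership[gene_index[g], p] = 1.0
    counts = membership.sum(axis=1)
    counts[counts == 0] = 1.0
    values += (membership @ activities.T) / counts[:, None]
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    return values


def _apply_batch_effects(
    values: np.ndarray,
    batches: list[str],
    shift: dict[str, np.ndarray],
    scale: dict[str, np.ndarray],
) -> np.ndarray:
    out = values.copy()
    for j, b in enumerate(batches):
        out[:, j] = out[:, j] * scale[b] + shift[b]
    return out


def _make_ppi(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pathways: GeneSetCollection,
    genes: list[str],
) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    p_within, p_across = 0.3, 0.01
    gene_arr = np.array(genes)
    for name in pathways.names:
        members = sorted(pathways[name])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_within:
                    graph.add_edge(members[i], members[j], weight=round(rng.uniform(0.5, 1.0), 4))
    n_across = int(p_across * len(genes) ** 2 / 2)
    for _ in range(n_across):
        a, b = rng.choice(gene_arr, size=2, replace=False)
        if not graph.has_edge(a, b):
            graph.add_edge(a, b, weight=round(rng.uniform(0.1, 0.5), 4))
    return graph


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Generate the full synthetic study: expression for cells and tumors
    (with planted batch effects), pathways, drugs, PPI graph, responses and
    ground truth. Bit-for-bit reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    pathways = _make_pathways(cfg, rng)
    pw_names = pathways.names

    baseline = rng.normal(5.0, 1.0, size=cfg.n_genes)

    cell_ids = [f"CL{i:04d}" for i in range(cfg.n_cell_samples)]
    tumor_ids = [f"TU{i:04d}" for i in range(cfg.n_tumor_samples)]
    a_cells = rng.normal(0.0, 1.0, size=(cfg.n_cell_samples, cfg.n_pathways))
    a_tumors = rng.normal(0.0, 1.0, size=(cfg.n_tumor_samples, cfg.n_pathways))

    cell_values = _expression_for(cfg, rng, pathways, gene_index, a_cells, baseline)
    tumor_values = _expression_for(cfg, rng, pathways, gene_index, a_tumors, baseline)

    cell_batches = [f"cells{i % cfg.n_batches}" for i in range(cfg.n_cell_samples)]
    batch_names = sorted(set(cell_batches)) + ["tumor"]
    lo_s, hi_s = cfg.batch_scale_range
    shift = {b: rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes) for b in batch_names}
    scale = {b: rng.uniform(lo_s, hi_s, size=cfg.n_genes) for b in batch_names}
    cell_values = _apply_batch_effects(cell_values, cell_batches, shift, scale)
    tumor_values = _apply_batch_effects(
        tumor_values, ["tumor"] * cfg.n_tumor_samples, shift, scale
    )

    cancer_pool = ["BRCA", "LUAD", "COAD", "SKCM"]
    cell_cancer = [cancer_pool[i % len(cancer_pool)] for i in range(cfg.n_cell_samples)]
    tumor_cancer = [cancer_pool[i % len(cancer_pool)] for i in range(cfg.n_tumor_samples)]

    cells = ExpressionMatrix(cell_values, genes, cell_ids, cell_batches, cell_cancer)
    tumors = ExpressionMatrix(
        tumor_values, genes, tumor_ids, ["tumor"] * cfg.n_tumor_samples, tumor_cancer
    )

    ppi = _make_ppi(cfg, rng, pathways, genes)

    # drugs: signal pathways, signed weights, targets drawn from signal pathways
    drugs: list[DrugRecord] = []
    signal: dict[str, dict[str, float]] = {}
    intercepts: dict[str, float] = {}
    w_scale = cfg.effect_size / np.sqrt(cfg.n_signal_pathways_per_drug)
    for d in range(cfg.n_drugs):
        drug_id = f"D{d:03d}"
        chosen = rng.choice(cfg.n_pathways, size=cfg.n_signal_pathways_per_drug, replace=False)
        weights = {
            pw_names[p]: float(rng.choice([-1.0, 1.0]) * w_scale * rng.uniform(0.8, 1.2))
            for p in chosen
        }
        targets: set[str] = set()
        for p in chosen:
            members = sorted(pathways[pw_names[p]])
            k = min(2, len(members))
            targets |= {members[i] for i in rng.choice(len(members), size=k, replace=False)}
        smiles = _SCAFFOLDS[d % len(_SCAFFOLDS)] + "C" * (d // len(_SCAFFOLDS))
        drugs.append(DrugRecord(drug_id, smiles, targets))
        signal[drug_id] = weights
        intercepts[drug_id] = float(rng.normal(0.0, 0.3))

    def _responses(activities: np.ndarray, sample_ids: list[str]) -> pd.DataFrame:
        rows = []
        for drug in drugs:
            w = np.array([signal[drug.drug_id].get(p, 0.0) for p in pw_names])
            z = activities @ w + intercepts[drug.drug_id]
            resp = _logistic(z) + rng.normal(0.0, cfg.noise_sd, size=len(z))
            resp = np.clip(resp, 0.0, 1.0)
            for s, r in zip(sample_ids, resp):
                rows.append((s, drug.drug_id, float(r)))
        return pd.DataFrame(rows, columns=["sample_id", "drug_id", "outcome"])

    cell_cont = ResponseTable(_responses(a_cells, cell_ids), "continuous")
    tumor_cont_df = _responses(a_tumors, tumor_ids)
    tumor_cont = ResponseTable(tumor_cont_df.copy(), "continuous")
    dich = tumor_cont_df.copy()
    med = dich.groupby("drug_id")["outcome"].transform("median")
    dich["outcome"] = (dich["outcome"] > med).astype(float)
    tumor_dich = ResponseTable(dich, "dichotomous")

    truth = GroundTruth(
        signal_pathways=signal,
        drug_intercepts=intercepts,
        cell_activities=pd.DataFrame(a_cells, index=cell_ids, columns=pw_names),
        tumor_activities=pd.DataFrame(a_tumors, index=tumor_ids, columns=pw_names),
    )
    return Cohort(
        cells, tumors, pathways, drugs, ppi, cell_cont, tumor_dich, tumor_cont, truth
    )


def make_imbalanced(
    table: ResponseTable, responder_fraction: float, seed: int = 0
) -> ResponseTable:
    """Downsample responders per drug so they make up ``responder_fraction``
    of that drug's rows (emulating heavily imbalanced xenograft panels)."""
    if not 0.0 < responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in (0, 1]")
    if table.outcome_kind != "dichotomous":
        raise ValueError("make_imbalanced requires a dichotomous table")
    rng = np.random.default_rng(seed)
    kept = []
    for _, sub in table.frame.groupby("drug_id", sort=True):
        n_target = int(round(responder_fraction * len(sub)))
        resp = sub[sub["outcome"] == 1.0]
        nonresp = sub[sub["outcome"] == 0.0]
        n_keep = min(len(resp), n_target)
        idx = rng.choice(resp.index.to_numpy(), size=n_keep, replace=False)
        kept.append(resp.loc[np.sort(idx)])
        kept.append(nonresp)
    out = pd.concat(kept).sort_values(["drug_id", "sample_id"]).reset_index(drop=True)
    return ResponseTable(out, "dichotomous")
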