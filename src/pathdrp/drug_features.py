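"""Drug feature blocks: chemical structure (CHEM) and propagated target
influence (DGNet).

CHEM is a 256-bit folded Morgan (circular, ECFP-style) fingerprint of the
drug's canonical SMILES. DGNet quantifies how strongly a drug's therapeutic
targets influence each pathway: a random walk with restart (RWR) from the
target genes over the protein-protein interaction network yields a
stationary visiting probability per gene; each pathway's raw score is the
mean probability over its member genes, and the score is z-normalized
against a permutation null of equal-size random target sets.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.linalg import lu_factor, lu_solve

from pathdrp.io_formats import DrugRecord, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["ChemFingerprint", "DGNetVector", "morgan_fingerprint", "rwr_propagate", "netpea_scores"]


@dataclasses.dataclass
class ChemFingerprint:
    bits: np.ndarray  # uint8 {0,1}, length n_bits
    radius: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, [0, 1]).all():
            raise ValueError("fingerprint bits must be 0/1")


@dataclasses.dataclass
class DGNetVector:
    scores: np.ndarray  # per-pathway z-score
    pathway_names: list[str]
    targets_in_graph: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("DGNet scores must be finite")


def morgan_fingerprint(
    smiles: str, radius: int = 2, n_bits: int = 256, drug_id: str | None = None
) -> ChemFingerprint:
    """Folded circular fingerprint of a SMILES string (default 256 bits,
    radius 2 — ECFP4-equivalent)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for drug {drug_id!r}" if drug_id else ""
        raise ValueError(f"invalid SMILES {smiles!r}{who}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=np.uint8)
    for b in fp.GetOnBits():
        bits[b] = 1
    return ChemFingerprint(bits, radius)


def _transition_matrix(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Column-stochastic transition matrix; dangling columns restart uniformly."""
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    col_sums = adj.sum(axis=0)
    mat = np.zeros_like(adj)
    nonzero = col_sums > 0
    mat[:, nonzero] = adj[:, nonzero] / col_sums[nonzero]
    if (~nonzero).any():
        mat[:, ~nonzero] = 1.0 / len(nodes)
    return mat


def rwr_propagate(
    graph: nx.Graph,
    seed_genes: set[str],
    restart_prob: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    method: str = "power",
) -> dict[str, float]:
    """Random walk with restart from ``seed_genes``.

    Solves p = r*e + (1-r)*M p with column-stochastic M and uniform restart
    vector e over the seeds, by power iteration (L1 tolerance ``tol``) or a
    direct linear solve. The result is a probability vector (sums to 1).
    """
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must be in (0, 1]")
    nodes = sorted(graph.nodes)
    seeds = sorted(set(seed_genes) & set(nodes))
    if not seeds:
        raise ValueError("no seed gene present in the graph")
    index = {g: i for i, g in enumerate(nodes)}
    e = np.zeros(len(nodes))
    e[[index[s] for s in seeds]] = 1.0 / len(seeds)
    mat = _transition_matrix(graph, nodes)

    if method == "direct":
        lhs = np.eye(len(nodes)) - (1.0 - restart_prob) * mat
        p = np.linalg.solve(lhs, restart_prob * e)
    elif method == "power":
        p = e.copy()
        for _ in range(max_iter):
            p_new = restart_prob * e + (1.0 - restart_prob) * (mat @ p)
            resid = np.abs(p_new - p).sum()
            p = p_new
            if resid < tol:
                break
        else:
            raise RuntimeError(f"RWR did not converge (L1 residual {resid:.3e})")
    else:
        raise ValueError(f"unknown method {method!r}")
    return {g: float(p[index[g]]) for g in nodes}


def netpea_scores(
    graph: nx.Graph,
    drug: DrugRecord,
    collection: GeneSetCollection,
    restart_prob: float = 0.5,
    n_perm: int = 200,
    seed: int = 0,
) -> DGNetVector:
    """DGNet vector of a drug: per-pathway z-score of the mean RWR visiting
    probability of its targets against equal-size random target sets.

    Drugs with no target in the graph get an all-zero vector (flagged);
    pathways with no gene in the graph are imputed to 0 with a warning.
    """
    nodes = sorted(graph.nodes)
    names = collection.names
    seeds = sorted(drug.targets & set(nodes))
    if not seeds:
        logger.warning("drug %r has no target in the PPI graph; DGNet zeroed", drug.drug_id)
        return DGNetVector(np.zeros(len(names)), list(names), targets_in_graph=False)

    index = {g: i for i, g in enumerate(nodes)}
    mat = _transition_matrix(graph, nodes)
    lhs = np.eye(len(nodes)) - (1.0 - restart_prob) * mat
    lu, piv = lu_factor(lhs)

    def solve(seed_idx: np.ndarray) -> np.ndarray:
        e = np.zeros(len(nodes))
        e[seed_idx] = 1.0 / len(seed_idx)
        return lu_solve((lu, piv), restart_prob * e)

    member_idx = []
    for name in names:
        idx = np.array([index[g] for g in sorted(collection[name]) if g in index], dtype=int)
        if len(idx) == 0:
            logger.warning("pathway %r has no gene in the graph; score imputed to 0", name)
        member_idx.append(idx)

    p_obs = solve(np.array([index[s] for s in seeds]))
    raw = np.array([p_obs[idx].mean() if len(idx) else np.nan for idx in member_idx])

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(names)))
    for t in range(n_perm):
        rand_idx = rng.choice(len(nodes), size=len(seeds), replace=False)
        p_null = solve(rand_idx)
        null[t] = [p_null[idx].mean() if len(idx) else np.nan for idx in member_idx]

    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.zeros(len(names))
    ok = np.isfinite(raw) & (sd > 1e-300)
    z[ok] = (raw[ok] - mu[ok]) / sd[ok]
    return DGNetVector(z, list(names), targets_in_graph=True)
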