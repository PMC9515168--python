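"""Readers, writers and in-memory containers for every external format.

All tabular formats are plain TSV/CSV handled through pandas; gene-set
collections travel as GMT (the MSigDB dialect: name, description, genes...);
protein-protein interaction networks as 3-column weighted edge lists loaded
into a networkx Graph. Gene identifiers are opaque symbols — no alias
resolution is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "DrugRecord",
    "ResponseTable",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_drug_table",
    "write_drug_table",
    "read_response_table",
    "write_response_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass
class ExpressionMatrix:
    """genes x samples matrix of log-scale expression with sample metadata.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
    gene_ids, sample_ids : ordered unique identifier lists
    batch, cancer_type : per-sample categorical labels
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    batch: list[str]
    cancer_type: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.batch = list(self.batch)
        self.cancer_type = list(self.cancer_type)
        n_g, n_s = self.values.shape
        if len(self.gene_ids) != n_g:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {n_g} rows")
        if len(self.sample_ids) != n_s:
            raise FormatError(f"{len(self.sample_ids)} sample ids for {n_s} columns")
        if len(set(self.gene_ids)) != n_g:
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        if len(self.batch) != n_s or len(self.cancer_type) != n_s:
            raise FormatError("batch / cancer_type length must equal sample count")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), self.sample_ids, self.batch, self.cancer_type
        )


@dataclasses.dataclass
class GeneSetCollection:
    """Named pathways, each a non-empty set of gene symbols."""

    sets: dict[str, set[str]]
    provenance: str = "SYNTHETIC"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set: {name}")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclasses.dataclass
class DrugRecord:
    """One drug: identifier, canonical SMILES, and a (possibly empty) target set."""

    drug_id: str
    smiles: str
    targets: set[str]


@dataclasses.dataclass
class ResponseTable:
    """Rows of (sample_id, drug_id, outcome).

    outcome_kind is "dichotomous" ({0,1} labels) or "continuous"
    (sensitivity in [0,1], e.g. 1-AUC of the dose-response curve).
    """

    frame: pd.DataFrame  # columns: sample_id, drug_id, outcome
    outcome_kind: str

    def __post_init__(self) -> None:
        required = {"sample_id", "drug_id", "outcome"}
        if not required.issubset(self.frame.columns):
            raise FormatError(f"response table needs columns {sorted(required)}")
        if self.outcome_kind not in ("dichotomous", "continuous"):
            raise FormatError(f"unknown outcome_kind {self.outcome_kind!r}")
        dup = self.frame.duplicated(subset=["sample_id", "drug_id"])
        if dup.any():
            raise FormatError("duplicate (sample_id, drug_id) pair in response table")
        out = self.frame["outcome"].to_numpy(dtype=float)
        if self.outcome_kind == "dichotomous":
            if not np.isin(out, [0.0, 1.0]).all():
                raise FormatError("dichotomous outcomes must be 0/1")
        else:
            if out.min() < 0.0 or out.max() > 1.0:
                raise FormatError("continuous outcomes must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, provenance: str = "FILE") -> GeneSetCollection:
    """Read a GMT gene-set file: name <TAB> description <TAB> gene...

    Duplicate genes within a line are deduplicated; the description field is
    discarded. Lines with fewer than 3 fields and duplicate pathway names are
    errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = set(g for g in fields[2:] if g)
            if not sets[name]:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
    return GeneSetCollection(sets, provenance=provenance)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            genes = sorted(collection[name])
            fh.write("\t".join([name, "na"] + genes) + "\n")


# ---------------------------------------------------------------------------
# Expression + sample annotation


def read_expression(
    path: str | Path,
    annot_path: str | Path | None = None,
    log_transform: bool = False,
    orient: str = "genes_in_rows",
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a gene x sample expression TSV/CSV with a header row.

    With ``log_transform`` values are replaced by log2(x + 1). Batch and
    cancer-type labels come from a sample-annotation TSV (columns sample_id,
    batch, cancer_type) keyed by sample id; absent, every sample gets batch
    "b0" and cancer type "NA".
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orient == "samples_in_rows":
        df = df.T
    elif orient != "genes_in_rows":
        raise FormatError(f"unknown orientation {orient!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene row(s): {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression cell: {exc}") from exc
    if log_transform:
        if (values < 0).any():
            raise FormatError("negative raw values cannot be log-transformed")
        values = np.log2(values + 1.0)
    sample_ids = [str(c) for c in df.columns]
    if annot_path is not None:
        annot = pd.read_csv(annot_path, sep="\t", dtype=str).set_index("sample_id")
        missing = [s for s in sample_ids if s not in annot.index]
        if missing:
            raise FormatError(f"samples missing from annotation: {missing[:5]}")
        batch = [annot.loc[s, "batch"] for s in sample_ids]
        cancer = [annot.loc[s, "cancer_type"] for s in sample_ids]
    else:
        batch = ["b0"] * len(sample_ids)
        cancer = ["NA"] * len(sample_ids)
    return ExpressionMatrix(values, [str(g) for g in df.index], sample_ids, batch, cancer)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, annot_path: str | Path | None = None
) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    if annot_path is not None:
        pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "batch": matrix.batch,
                "cancer_type": matrix.cancer_type,
            }
        ).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI edge list


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a 3-column TSV (geneA, geneB, weight >= 0) into an undirected graph.

    Repeated edges keep the maximum weight; self-loops are dropped.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, w_str = fields
            try:
                w = float(w_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric weight {w_str!r}") from exc
            if w < 0:
                raise FormatError(f"{path}:{lineno}: negative edge weight {w}")
            if a == b:
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
            else:
                graph.add_edge(a, b, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0)}\n")
        # isolated nodes survive round-trip as self-loop lines (dropped on read)
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\t{node}\t0\n")


# ---------------------------------------------------------------------------
# Drug table


def read_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read a TSV with columns drug_id, smiles, targets (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise FormatError(f"drug table missing column {col!r}")
    if "targets" not in df.columns:
        df["targets"] = ""
    if df["drug_id"].duplicated().any():
        dups = df["drug_id"][df["drug_id"].duplicated()].tolist()
        raise FormatError(f"repeated drug_id(s): {dups}")
    records = []
    for _, row in df.iterrows():
        targets = set(t for t in str(row["targets"]).split(";") if t)
        records.append(DrugRecord(row["drug_id"], row["smiles"], targets))
    return records


def write_drug_table(drugs: list[DrugRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "smiles": [d.smiles for d in drugs],
            "targets": [";".join(sorted(d.targets)) for d in drugs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Response table


def read_response_table(path: str | Path, outcome_kind: str) -> ResponseTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug_id": str})
    return ResponseTable(df[["sample_id", "drug_id", "outcome"]].copy(), outcome_kind)


def write_response_table(table: ResponseTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
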