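"""Readers, writers and the shared data model.

Expression values are assumed to be log-normalized abundances as provided
by upstream processing; no normalization is performed here. The internal
orientation is always genes x cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FlowRouteError(Exception):
    """Base class for user-facing errors."""


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of log-normalized expression values.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Non-negative log-normalized expression.
    gene_ids : list of str
        Unique gene identifiers, one per row.
    cell_ids : list of str
        Unique cell identifiers, one per column.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FlowRouteError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FlowRouteError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FlowRouteError("duplicate gene ids (collapse them with read_expression)")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FlowRouteError("duplicate cell ids")
        if np.isnan(self.values).any():
            raise FlowRouteError("NaN values in expression matrix are not supported")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression series of one gene across all cells."""
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise FlowRouteError(f"unknown gene: {gene_id}") from None
        return self.values[i]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise FlowRouteError(f"unknown genes: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.cell_ids))

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in idx]
        if missing:
            raise FlowRouteError(f"unknown cells: {missing[:5]}")
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(cells))


@dataclass
class Embedding:
    """Cells x d low-dimensional coordinates (PCA, t-SNE, diffusion map, ...)."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.coords.ndim != 2:
            raise FlowRouteError("embedding coordinates must be a 2-D matrix")
        if self.coords.shape[0] != len(self.cell_ids):
            raise FlowRouteError("embedding rows do not match cell ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FlowRouteError("duplicate cell ids in embedding")
        if np.isnan(self.coords).any():
            raise FlowRouteError("NaN values in embedding are not supported")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class RegulatorList:
    """Gene symbols designated as transcriptional regulators (e.g. a TF catalogue)."""

    genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {str(g) for g in self.genes}

    def intersect(self, gene_ids: list[str]) -> "RegulatorList":
        return RegulatorList(self.genes & set(gene_ids))

    def __len__(self) -> int:
        return len(self.genes)


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # duplicates averaged; first-occurrence order preserved
    if df.index.is_unique:
        return df
    order = df.index.drop_duplicates()
    return df.groupby(level=0, sort=False).mean().loc[order]


def read_expression(path, fmt: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV (gene rows, header of cell ids)
    or MatrixMarket MTX with companion ``genes.tsv``/``barcodes.tsv`` files.

    Duplicate gene symbols are collapsed by averaging. ``transpose`` flips a
    cells x genes file into the internal genes x cells orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FlowRouteError(f"no such file: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise FlowRouteError(f"cannot infer format from suffix {suffix!r}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        # parse the header ourselves: pandas would mangle duplicate ids
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        df = pd.read_csv(path, sep=sep, index_col=0, header=None, skiprows=1)
        if len(header) - 1 != df.shape[1]:
            raise FlowRouteError(f"{path}: header has {len(header) - 1} ids for {df.shape[1]} columns")
        df.columns = [str(c) for c in header[1:]]
        df.index = df.index.astype(str)
    elif fmt == "mtx":
        genes_file = path.with_name("genes.tsv")
        cells_file = path.with_name("barcodes.tsv")
        for f in (genes_file, cells_file):
            if not f.exists():
                raise FlowRouteError(f"companion id file missing: {f}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [line.split("\t")[0] for line in genes_file.read_text().split("\n") if line.strip()]
        cells = [line.split("\t")[0] for line in cells_file.read_text().split("\n") if line.strip()]
        if mat.shape != (len(genes), len(cells)):
            raise FlowRouteError(
                f"mtx shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise FlowRouteError(f"unknown format: {fmt}")
    if transpose:
        df = df.T
    if np.isnan(df.to_numpy()).any():
        raise FlowRouteError(f"{path} contains missing values; NaN is not supported")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise FlowRouteError(f"duplicate cell ids: {dupes[:5]}")
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns))


def read_embedding(path, transpose: bool = False) -> Embedding:
    """Read a cells x d embedding CSV with a first column of cell ids."""
    path = Path(path)
    if not path.exists():
        raise FlowRouteError(f"no such file: {path}")
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    return Embedding(df.to_numpy(dtype=float), [str(c) for c in df.index])


def write_embedding(emb: Embedding, path) -> None:
    pd.DataFrame(
        emb.coords, index=emb.cell_ids, columns=[f"dim{i + 1}" for i in range(emb.dim)]
    ).to_csv(path)


def read_regulators(path) -> RegulatorList:
    """Read a one-symbol-per-line regulator list."""
    path = Path(path)
    if not path.exists():
        raise FlowRouteError(f"no such file: {path}")
    genes = {line.strip() for line in path.read_text().split("\n") if line.strip()}
    return RegulatorList(genes)


def write_expression(expr: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    expr.to_frame().to_csv(path, sep=sep)


def filter_zero_variance(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero variance across cells; the cell set is unchanged."""
    keep = expr.values.var(axis=1) > 0
    if not keep.any():
        raise FlowRouteError("all genes have zero variance; nothing left to analyze")
    return ExpressionMatrix(
        expr.values[keep],
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.cell_ids),
    )


def write_graph(graph, path) -> None:
    """Write a cell graph as GraphML (node attribute ``subpopulation``,
    edge attribute ``weight``)."""
    g = graph.graph.copy()
    if graph.subpopulations is not None:
        nx.set_node_attributes(g, graph.subpopulations, "subpopulation")
    g.graph["kind"] = graph.kind
    g.graph["k_used"] = graph.k
    if graph.neighbor_sets is not None:
        for node, nbrs in graph.neighbor_sets.items():
            g.nodes[node]["neighbor_set"] = "|".join(sorted(nbrs))
    nx.write_graphml(g, path)


def read_graph(path):
    from .graph import CellGraph  # avoid import cycle

    path = Path(path)
    if not path.exists():
        raise FlowRouteError(f"no such file: {path}")
    g = nx.read_graphml(path)
    kind = g.graph.pop("kind", "similarity")
    k = int(g.graph.pop("k_used", 0))
    subpops = {}
    neighbor_sets = {}
    for node, data in g.nodes(data=True):
        if "subpopulation" in data:
            subpops[node] = int(data.pop("subpopulation"))
        if "neighbor_set" in data:
            neighbor_sets[node] = frozenset(data.pop("neighbor_set").split("|"))
    return CellGraph(
        graph=g,
        kind=kind,
        k=k,
        neighbor_sets=neighbor_sets or None,
        subpopulations=subpops or None,
    )


def write_trajectory(traj, path) -> None:
    """Write a trajectory as a JSON record (ordered cells, pseudotime, flow,
    cost, length, endpoint subpopulations)."""
    record = {
        "source_subpop": traj.source_subpop,
        "target_subpop": traj.target_subpop,
        "cells": list(traj.cells),
        "pseudotime": [traj.pseudotime[c] for c in traj.cells],
        "flow": traj.flow,
        "cost": traj.cost,
        "length": traj.length,
    }
    Path(path).write_text(json.dumps(record, indent=1))


def read_trajectory(path):
    from .flownet import Trajectory

    path = Path(path)
    if not path.exists():
        raise FlowRouteError(f"no such file: {path}")
    record = json.loads(path.read_text())
    return Trajectory(
        cells=list(record["cells"]),
        flow=float(record["flow"]),
        cost=float(record["cost"]),
        length=int(record["length"]),
        pseudotime=dict(zip(record["cells"], record["pseudotime"])),
        source_subpop=record["source_subpop"],
        target_subpop=record["target_subpop"],
    )
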