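"""kNN graph construction, Jaccard reweighting, subpopulation detection and
subpopulation gene signatures.

The graph is built from a low-dimensional embedding: each cell is connected
to its k nearest neighbors by Euclidean distance; the resulting distance
graph is then transformed into a similarity graph by the Jaccard index of
shared neighborhoods, which strengthens within-subpopulation edges and
prunes spurious ones. Communities of the similarity graph define
subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import binom

from .io import Embedding, ExpressionMatrix, FlowRouteError


@dataclass
class CellGraph:
    """A weighted graph over cells.

    ``kind`` is ``"distance"`` straight after kNN construction (directed,
    weights are Euclidean distances) and ``"similarity"`` after the Jaccard
    transform (undirected, weights in (0, 1]).
    """

    graph: nx.Graph | nx.DiGraph
    kind: str
    k: int
    neighbor_sets: dict[str, frozenset] | None = None
    subpopulations: dict[str, int] | None = None

    @property
    def cells(self) -> list[str]:
        return list(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]


@dataclass
class SubpopulationAssignment:
    """Cell -> subpopulation labels; labels are contiguous integers from 1,
    numbered by decreasing subpopulation size."""

    labels: dict[str, int]
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            sizes: dict[int, int] = {}
            for lab in self.labels.values():
                sizes[lab] = sizes.get(lab, 0) + 1
            self.sizes = sizes

    def members(self, label: int) -> list[str]:
        return [c for c, lab in self.labels.items() if lab == label]

    @property
    def n_subpopulations(self) -> int:
        return len(self.sizes)


def build_knn_graph(emb: Embedding, k: int) -> CellGraph:
    """Connect each cell to its k nearest neighbors (Euclidean distance).

    Returns a directed distance graph with out-degree exactly k per node.
    Distance ties are broken by ascending cell-id order so the construction
    is reproducible regardless of input order.
    """
    n = emb.n_cells
    if k <= 0:
        raise FlowRouteError(f"k must be positive, got {k}")
    if k >= n:
        raise FlowRouteError(f"k={k} requires at least {k + 1} cells, got {n}")
    dists = cdist(emb.coords, emb.coords)
    # rank of each cell id in sorted-id order, used as the tie-break key
    id_rank = np.argsort(np.argsort(emb.cell_ids, kind="stable"), kind="stable")
    g = nx.DiGraph()
    g.add_nodes_from(emb.cell_ids)
    neighbor_sets: dict[str, frozenset] = {}
    for i, cell in enumerate(emb.cell_ids):
        order = np.lexsort((id_rank, dists[i]))
        picked = [j for j in order if j != i][:k]
        for j in picked:
            g.add_edge(cell, emb.cell_ids[j], weight=float(dists[i, j]))
        neighbor_sets[cell] = frozenset([cell] + [emb.cell_ids[j] for j in picked])
    return CellGraph(graph=g, kind="distance", k=k, neighbor_sets=neighbor_sets)


def jaccard_transform(graph: CellGraph) -> CellGraph:
    """Reweight kNN edges by the Jaccard index of the two endpoints'
    neighbor sets (each set includes the node itself).

    Zero-similarity edges are removed; the result is undirected (an edge is
    kept if it was present in either direction).
    """
    if graph.kind != "similarity" and graph.neighbor_sets is None:
        raise FlowRouteError("jaccard_transform requires a kNN graph with neighbor sets")
    if graph.kind == "similarity":
        raise FlowRouteError("graph is already a similarity graph")
    nsets = graph.neighbor_sets
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    for u, v in graph.graph.edges:
        if g.has_edge(u, v):
            continue
        inter = len(nsets[u] & nsets[v])
        union = len(nsets[u] | nsets[v])
        jac = inter / union
        if jac > 0:
            g.add_edge(u, v, weight=jac)
    return CellGraph(
        graph=g,
        kind="similarity",
        k=graph.k,
        neighbor_sets=graph.neighbor_sets,
        subpopulations=graph.subpopulations,
    )


def find_subpopulations(graph: CellGraph, seed: int = 0) -> SubpopulationAssignment:
    """Partition the similarity graph into subpopulations by Louvain
    modularity optimization. Deterministic for a given seed; isolated cells
    become singleton subpopulations. Labels are renumbered by decreasing
    subpopulation size (ties broken by smallest member id)."""
    if graph.kind != "similarity":
        raise FlowRouteError("community detection requires a similarity graph")
    if graph.graph.number_of_nodes() == 0:
        raise FlowRouteError("empty graph")
    communities = nx.community.louvain_communities(graph.graph, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = {cell: i + 1 for i, comm in enumerate(communities) for cell in comm}
    graph.subpopulations = labels
    return SubpopulationAssignment(labels=labels)


def signature_genes(
    expr: ExpressionMatrix,
    assign: SubpopulationAssignment,
    min_fold: float = 1.5,
) -> pd.DataFrame:
    """Subpopulation-specific gene signatures by a binomial counting
    statistic on expressing cells.

    For gene g and subpopulation P: K = number of cells in P expressing g
    (value > 0), N = |P|, q = expressing fraction among cells outside P.
    Enrichment p-value is the upper binomial tail P(X >= K | N, q);
    depletion the lower tail. Direction follows the sign of the mean
    expression difference, and only genes whose expm1-scale mean fold
    change passes ``min_fold`` are reported.

    Returns a DataFrame with columns subpopulation, gene, direction, p_value.
    """
    missing = [c for c in expr.cell_ids if c not in assign.labels]
    if missing:
        raise FlowRouteError(f"cells without subpopulation label: {missing[:5]}")
    for lab, size in assign.sizes.items():
        if size < 2:
            raise FlowRouteError(f"subpopulation {lab} has fewer than 2 cells")
    expressed = expr.values > 0
    cell_index = {c: j for j, c in enumerate(expr.cell_ids)}
    rows = []
    for lab in sorted(assign.sizes):
        in_cols = [cell_index[c] for c in assign.members(lab) if c in cell_index]
        out_cols = [j for j in range(expr.n_cells) if j not in set(in_cols)]
        if not out_cols:
            continue
        k_in = expressed[:, in_cols].sum(axis=1)
        n_in = len(in_cols)
        q = expressed[:, out_cols].mean(axis=1)
        mean_in = np.expm1(expr.values[:, in_cols]).mean(axis=1)
        mean_out = np.expm1(expr.values[:, out_cols]).mean(axis=1)
        eps = 1e-9
        fold = (mean_in + eps) / (mean_out + eps)
        enriched = mean_in >= mean_out
        p_enrich = binom.sf(k_in - 1, n_in, q)
        p_deplete = binom.cdf(k_in, n_in, q)
        for gi, gene in enumerate(expr.gene_ids):
            if enriched[gi]:
                if fold[gi] < min_fold:
                    continue
                rows.append((lab, gene, "enriched", float(p_enrich[gi])))
            else:
                if fold[gi] > 1.0 / min_fold:
                    continue
                rows.append((lab, gene, "depleted", float(p_deplete[gi])))
    return pd.DataFrame(rows, columns=["subpopulation", "gene", "direction", "p_value"])
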