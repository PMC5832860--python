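"""Trajectories as minimum-cost flows on the cell-cell similarity graph.

Each undirected similarity edge becomes two arcs whose capacity is the
Jaccard similarity and whose cost is -log(similarity), so that routing the
maximum flow at minimum cost prefers paths through phenotypically similar
cells. Auxiliary source/sink nodes turn the multi-source/multi-sink problem
into a single-commodity one. The optimal flow is decomposed into simple
paths and the top-ranked path is the trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import CellGraph, SubpopulationAssignment
from .io import ExpressionMatrix, FlowRouteError

SOURCE = "__source__"
SINK = "__sink__"

# integral solver granularity: capacities and costs are scaled to integers
CAPACITY_SCALE = 10**6
COST_SCALE = 10**6

RANK_CRITERIA = ("flow_per_length", "cost", "flow", "length")


@dataclass
class FlowProblem:
    """A directed flow network with auxiliary source and sink.

    Real arcs carry capacity = similarity in (0, 1] and cost = -log(capacity);
    auxiliary arcs (source -> each member of S, each member of T -> sink)
    carry capacity 1 and cost 0.
    """

    network: nx.DiGraph
    sources: frozenset
    sinks: frozenset

    @property
    def n_nodes(self) -> int:
        return self.network.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.network.number_of_edges()


@dataclass
class FlowSolution:
    flow: dict  # (u, v) -> flow value
    total_flow: float
    total_cost: float
    connected: bool = True


@dataclass
class Trajectory:
    """An ordered source-to-target cell path with uniform pseudotime."""

    cells: list[str]
    flow: float
    cost: float
    length: int
    pseudotime: dict[str, float]
    source_subpop: int | None = None
    target_subpop: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            raise FlowRouteError("trajectory revisits a cell")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _check_similarity_graph(graph: CellGraph) -> None:
    if graph.kind != "similarity":
        raise FlowRouteError("flow analysis requires a similarity graph")
    for u, v, w in graph.graph.edges(data="weight"):
        if not (0 < w <= 1):
            raise FlowRouteError(f"edge ({u},{v}) weight {w} outside (0, 1]")


def _cost_graph(graph: CellGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    for u, v, w in graph.graph.edges(data="weight"):
        g.add_edge(u, v, cost=-math.log(w))
    return g


def select_source_target(
    graph: CellGraph,
    assign: SubpopulationAssignment,
    a: int,
    b: int,
) -> tuple[str, str]:
    """Pick the most distant (source, target) cell pair between two
    subpopulations: among all shortest paths (distance = -log similarity)
    from each a-cell to each b-cell, return the endpoints of the longest
    one. Ties break to the lexicographically smallest (source, target) pair.
    """
    if a == b:
        raise FlowRouteError(f"source and target subpopulations are identical ({a})")
    a_cells = sorted(assign.members(a))
    b_cells = set(assign.members(b))
    if not a_cells or not b_cells:
        raise FlowRouteError(f"empty subpopulation in pair ({a}, {b})")
    _check_similarity_graph(graph)
    g = _cost_graph(graph)
    best: tuple[str, str] | None = None
    best_dist = -np.inf
    for src in a_cells:
        dists = nx.single_source_dijkstra_path_length(g, src, weight="cost")
        for tgt in sorted(b_cells):
            if tgt not in dists:
                continue
            d = dists[tgt]
            if d > best_dist + 1e-12 or (
                abs(d - best_dist) <= 1e-12 and best is not None and (src, tgt) < best
            ):
                best = (src, tgt)
                best_dist = d
    if best is None:
        comp_a = nx.node_connected_component(g, a_cells[0])
        raise FlowRouteError(
            f"subpopulations {a} and {b} are in different connected components "
            f"(component of subpopulation {a} has {len(comp_a)} cells, "
            f"graph has {g.number_of_nodes()}); increase the trajectory k"
        )
    return best


def build_flow_problem(graph: CellGraph, sources, sinks) -> FlowProblem:
    """Construct the directed flow network: each similarity edge becomes two
    opposite arcs (capacity = weight, cost = -log weight); auxiliary arcs
    connect the source node to every cell in ``sources`` and every cell in
    ``sinks`` to the sink node with capacity 1 and cost 0."""
    sources = frozenset(sources)
    sinks = frozenset(sinks)
    if sources & sinks:
        raise FlowRouteError(f"sources and sinks overlap: {sorted(sources & sinks)[:5]}")
    nodes = set(graph.graph.nodes)
    for cell in sources | sinks:
        if cell not in nodes:
            raise FlowRouteError(f"cell {cell} not in graph")
    _check_similarity_graph(graph)
    net = nx.DiGraph()
    net.add_nodes_from(graph.graph.nodes)
    for u, v, w in graph.graph.edges(data="weight"):
        cost = -math.log(w)
        net.add_edge(u, v, capacity=float(w), cost=cost)
        net.add_edge(v, u, capacity=float(w), cost=cost)
    for cell in sources:
        net.add_edge(SOURCE, cell, capacity=1.0, cost=0.0)
    for cell in sinks:
        net.add_edge(cell, SINK, capacity=1.0, cost=0.0)
    return FlowProblem(network=net, sources=sources, sinks=sinks)


def solve_min_cost_flow(problem: FlowProblem) -> FlowSolution:
    """Route the maximum source->sink flow at minimum total cost.

    Capacities and costs are scaled by 1e6 and rounded to integers for the
    combinatorial solver; flows are rescaled back and the reported cost is
    recomputed with exact -log costs.
    """
    scaled = nx.DiGraph()
    scaled.add_nodes_from(problem.network.nodes)
    for u, v, data in problem.network.edges(data=True):
        scaled.add_edge(
            u,
            v,
            capacity=int(round(data["capacity"] * CAPACITY_SCALE)),
            weight=int(round(data["cost"] * COST_SCALE)),
        )
    if not nx.has_path(scaled, SOURCE, SINK):
        return FlowSolution(flow={}, total_flow=0.0, total_cost=0.0, connected=False)
    flow_dict = nx.max_flow_min_cost(scaled, SOURCE, SINK, capacity="capacity", weight="weight")
    flow = {}
    total_cost = 0.0
    total_flow = 0.0
    for u, nbrs in flow_dict.items():
        for v, f in nbrs.items():
            if f > 0:
                fv = f / CAPACITY_SCALE
                flow[(u, v)] = fv
                total_cost += problem.network[u][v]["cost"] * fv
                if u == SOURCE:
                    total_flow += fv
    return FlowSolution(flow=flow, total_flow=total_flow, total_cost=total_cost)


def _widest_path(g: nx.DiGraph, source: str, sink: str) -> list[str] | None:
    """Maximum-bottleneck simple path via a max-min variant of Dijkstra."""
    import heapq

    width = {source: np.inf}
    prev: dict[str, str] = {}
    heap = [(-np.inf, source)]
    done = set()
    while heap:
        neg_w, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == sink:
            break
        for v, data in g[u].items():
            w = min(-neg_w, data["flow"])
            if w > width.get(v, 0.0):
                width[v] = w
                prev[v] = u
                heapq.heappush(heap, (-w, v))
    if sink not in done:
        return None
    path = [sink]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return path[::-1]


def decompose_flow(solution: FlowSolution, problem: FlowProblem) -> list[dict]:
    """Greedy widest-path decomposition of the flow support into simple
    source->sink paths. Each record carries the path's cells (auxiliary
    nodes stripped), its total flow (sum of the solution flow over its
    edges), cost, length and bottleneck."""
    support = nx.DiGraph()
    for (u, v), f in solution.flow.items():
        if f > 1e-12:
            support.add_edge(u, v, flow=f)
    residual = support.copy()
    paths = []
    while residual.has_node(SOURCE) and residual.has_node(SINK):
        path = _widest_path(residual, SOURCE, SINK)
        if path is None:
            break
        bottleneck = min(residual[u][v]["flow"] for u, v in zip(path, path[1:]))
        cells = [n for n in path if n not in (SOURCE, SINK)]
        real_edges = [
            (u, v) for u, v in zip(path, path[1:]) if u not in (SOURCE, SINK) and v not in (SOURCE, SINK)
        ]
        path_flow = sum(support[u][v]["flow"] for u, v in real_edges)
        path_cost = sum(problem.network[u][v]["cost"] for u, v in real_edges)
        paths.append(
            {
                "cells": cells,
                "flow": path_flow,
                "cost": path_cost,
                "length": len(real_edges),
                "bottleneck": bottleneck,
            }
        )
        for u, v in zip(path, path[1:]):
            residual[u][v]["flow"] -= bottleneck
            if residual[u][v]["flow"] <= 1e-12:
                residual.remove_edge(u, v)
    return paths


def _rank_key(record: dict, criterion: str):
    if criterion == "flow_per_length":
        return -(record["flow"] / max(record["length"], 1))
    if criterion == "cost":
        return record["cost"]
    if criterion == "flow":
        return -record["flow"]
    if criterion == "length":
        return -record["length"]  # longest path spans the full transition
    raise FlowRouteError(f"unknown ranking criterion: {criterion} (choose from {RANK_CRITERIA})")


def extract_and_rank_paths(
    solution: FlowSolution,
    problem: FlowProblem,
    criterion: str = "flow_per_length",
    source_subpop: int | None = None,
    target_subpop: int | None = None,
) -> Trajectory:
    """Decompose the optimal flow into simple paths, rank them by the chosen
    criterion (default: total flow normalized by path length) and return the
    top path as a Trajectory with uniformly spaced pseudotime on [0, 1]."""
    if solution.total_flow <= 0:
        raise FlowRouteError("no positive flow to decompose")
    paths = decompose_flow(solution, problem)
    if not paths:
        raise FlowRouteError("flow decomposition produced no source->sink path")
    paths.sort(key=lambda r: (_rank_key(r, criterion), r["cells"]))
    top = paths[0]
    cells = top["cells"]
    m = len(cells)
    pseudotime = {c: (i / (m - 1) if m > 1 else 0.0) for i, c in enumerate(cells)}
    return Trajectory(
        cells=cells,
        flow=top["flow"],
        cost=top["cost"],
        length=top["length"],
        pseudotime=pseudotime,
        source_subpop=source_subpop,
        target_subpop=target_subpop,
    )


@dataclass
class PairResult:
    pair: tuple[int, int]
    trajectory: Trajectory | None = None
    error: str | None = None


def trajectories_between(
    graph: CellGraph,
    assign: SubpopulationAssignment,
    expr: ExpressionMatrix | None,
    pairs: list[tuple[int, int]],
    criterion: str = "flow_per_length",
) -> list[PairResult]:
    """Run the full source-selection -> flow -> path-extraction pipeline for
    each (source subpopulation, target subpopulation) pair. Failures are
    reported per pair without aborting the batch."""
    results = []
    for a, b in pairs:
        try:
            src, tgt = select_source_target(graph, assign, a, b)
            problem = build_flow_problem(graph, {src}, {tgt})
            solution = solve_min_cost_flow(problem)
            if not solution.connected or solution.total_flow <= 0:
                raise FlowRouteError(f"no flow between subpopulations {a} and {b}")
            traj = extract_and_rank_paths(
                solution, problem, criterion, source_subpop=a, target_subpop=b
            )
            results.append(PairResult(pair=(a, b), trajectory=traj))
        except FlowRouteError as exc:
            results.append(PairResult(pair=(a, b), error=str(exc)))
    return results
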