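"""Independent reference implementations used for verification.

These deliberately avoid the algorithms used by the library proper: the
flow oracle enumerates integral path combinations by branch-and-bound, the
autocorrelation oracle is a literal double loop, and the Jaccard oracle
recomputes neighbor-set arithmetic from raw coordinates. They are meant for
small instances only.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .flownet import SINK, SOURCE, FlowProblem


def enumerate_min_cost_max_flow(
    problem: FlowProblem, unit: float = 0.1, max_paths: int = 200
) -> tuple[float, float]:
    """Exhaustively search integral combinations of simple source->sink
    paths for the maximum flow of minimum cost.

    Capacities must be integer multiples of ``unit``. Returns
    (max_flow, min_cost); cost uses the network's exact real arc costs.
    Raises ValueError when the instance has more than ``max_paths`` simple
    paths (keep oracle instances small).
    """
    net = problem.network
    paths = list(nx.all_simple_paths(net, SOURCE, SINK))
    if len(paths) > max_paths:
        raise ValueError(f"too many simple paths for enumeration: {len(paths)}")
    if not paths:
        return 0.0, 0.0
    residual = {}
    for u, v, data in net.edges(data=True):
        cap_units = data["capacity"] / unit
        if abs(cap_units - round(cap_units)) > 1e-9:
            raise ValueError(f"capacity {data['capacity']} is not a multiple of {unit}")
        residual[(u, v)] = int(round(cap_units))
    path_edges = [list(zip(p, p[1:])) for p in paths]
    path_cost = [sum(net[u][v]["cost"] for u, v in pe) for pe in path_edges]
    # cheap paths first so good solutions are found early and pruning bites
    order = sorted(range(len(paths)), key=lambda i: path_cost[i])
    path_edges = [path_edges[i] for i in order]
    path_cost = [path_cost[i] for i in order]
    # the max-flow VALUE is fixed first (standard augmenting-path max flow);
    # the enumeration then exhausts integral path combinations achieving it
    # and minimizes the exact real cost over them
    unit_graph = nx.DiGraph()
    for (u, v), cap in residual.items():
        unit_graph.add_edge(u, v, capacity=cap)
    max_units, _ = nx.maximum_flow(unit_graph, SOURCE, SINK)
    if max_units == 0:
        return 0.0, 0.0
    best = {"cost": np.inf}

    def rec(i: int, flow: int, cost: float) -> None:
        if cost >= best["cost"] - 1e-12:
            return
        if flow == max_units:
            best["cost"] = cost
            return
        if i == len(paths):
            return
        extra = sum(
            min(residual[e] for e in path_edges[j]) for j in range(i, len(paths))
        )
        if flow + extra < max_units:
            return
        # every missing unit costs at least the cheapest remaining path
        if cost + (max_units - flow) * path_cost[i] * unit >= best["cost"] - 1e-12:
            return
        b = min(residual[e] for e in path_edges[i])
        for f in range(b, -1, -1):
            for e in path_edges[i]:
                residual[e] -= f
            rec(i + 1, flow + f, cost + f * path_cost[i] * unit)
            for e in path_edges[i]:
                residual[e] += f

    rec(0, 0, 0.0)
    return max_units * unit, best["cost"]


def autocorrelation_double_loop(x, lag: int = 1) -> float:
    """Literal double-loop evaluation of r_t = c_t / c_0 with
    c_t = (1/n) * sum_s (x_{s+t} - xbar)(x_s - xbar)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = sum(x) / n

    def c(t: int) -> float:
        total = 0.0
        for s in range(max(1, -t), min(n - t, n) + 1):  # 1-based bounds
            total += (x[s + t - 1] - xbar) * (x[s - 1] - xbar)
        return total / n

    return c(lag) / c(0)


def jaccard_from_coords(coords: np.ndarray, cell_ids: list[str], k: int) -> dict:
    """Set-arithmetic Jaccard weights recomputed from scratch: neighbor sets
    are the k nearest cells by a naive all-pairs sort (ties by cell id),
    each set including the cell itself."""
    n = len(cell_ids)
    nsets = {}
    for i in range(n):
        d = [
            (float(np.linalg.norm(coords[i] - coords[j])), cell_ids[j])
            for j in range(n)
            if j != i
        ]
        d.sort()
        nsets[cell_ids[i]] = frozenset([cell_ids[i]] + [cid for _, cid in d[:k]])
    weights = {}
    for a, b in itertools.combinations(sorted(cell_ids), 2):
        inter = len(nsets[a] & nsets[b])
        union = len(nsets[a] | nsets[b])
        if inter:
            weights[(a, b)] = inter / union
    return weights


def random_flow_instance(seed: int, max_nodes: int = 8, path_cap: int = 20):
    """A small random similarity graph plus source/sink cells for the flow
    oracle; capacities are drawn from {0.1, ..., 1.0}. Instances with too
    many simple paths are resampled so enumeration stays tractable."""
    from .graph import CellGraph

    rng = np.random.default_rng(seed)
    for _ in range(100):
        n = int(rng.integers(4, max_nodes + 1))
        p = min(0.9, 2.2 / n + 0.15)
        g = nx.Graph()
        names = [f"n{i}" for i in range(n)]
        g.add_nodes_from(names)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.uniform() < p:
                    g.add_edge(names[i], names[j], weight=int(rng.integers(1, 11)) / 10.0)
        if g.number_of_edges() == 0:
            continue
        nodes = sorted(g.nodes)
        n_src = int(rng.integers(1, 3))
        n_snk = int(rng.integers(1, 3))
        if n_src + n_snk > n:
            continue
        chosen = rng.choice(len(nodes), size=n_src + n_snk, replace=False)
        sources = {nodes[i] for i in chosen[:n_src]}
        sinks = {nodes[i] for i in chosen[n_src:]}
        graph = CellGraph(graph=g, kind="similarity", k=0)
        from .flownet import build_flow_problem

        problem = build_flow_problem(graph, sources, sinks)
        n_paths = sum(1 for _ in itertools.islice(
            nx.all_simple_paths(problem.network, SOURCE, SINK), path_cap + 1
        ))
        if 0 < n_paths <= path_cap:
            return graph, sources, sinks, problem
    raise RuntimeError("could not sample a tractable flow instance")
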