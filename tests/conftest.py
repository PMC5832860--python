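import collections
from types import SimpleNamespace

import numpy as np
import pytest

import flowroute as fr


@pytest.fixture()
def tiny_embedding():
    """Three collinear cells at x = 0, 1, 10."""
    return fr.Embedding(np.array([[0.0], [1.0], [10.0]]), ["a", "b", "c"])


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(0)
    values = np.abs(rng.normal(1.0, 0.5, size=(20, 12)))
    return fr.ExpressionMatrix(
        values, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(12)]
    )


def _majority_branch(assign, truth):
    return {
        lab: collections.Counter(
            truth.branch_labels[c] for c in assign.members(lab)
        ).most_common(1)[0][0]
        for lab in assign.sizes
    }


def analyze_branching(expr, emb, truth, k_subpop=20, k_traj=10, seed=42):
    """Shared pipeline driver for simulated data: graph, subpopulations and
    the root/terminal subpopulation choices implied by the ground truth."""
    expr = fr.filter_zero_variance(expr)
    sim_sub = fr.jaccard_transform(fr.build_knn_graph(emb, k_subpop))
    assign = fr.find_subpopulations(sim_sub, seed=seed)
    sim_traj = fr.jaccard_transform(fr.build_knn_graph(emb, k_traj))
    t = truth.true_pseudotime
    maj = _majority_branch(assign, truth)
    mean_t = {
        lab: float(np.mean([t[c] for c in assign.members(lab)])) for lab in assign.sizes
    }
    terminals = {}
    for term in truth.terminal_branches:
        labs = [l for l in assign.sizes if maj[l] == term]
        if labs:
            terminals[term] = max(labs, key=mean_t.get)
    roots = {}
    for rb in truth.root_branches:
        labs = [l for l in assign.sizes if maj[l] == rb]
        if labs:
            roots[rb] = min(labs, key=mean_t.get)
    return SimpleNamespace(
        expr=expr,
        emb=emb,
        truth=truth,
        assign=assign,
        sim_traj=sim_traj,
        majority=maj,
        mean_t=mean_t,
        roots=roots,
        terminals=terminals,
    )


@pytest.fixture(scope="session")
def bifurcation_run():
    """The central bifurcating simulation (600 cells, 500 genes, seed 1)
    analyzed end to end: trajectory to branch B, smoothed dynamics, gene
    ranking and GRN regulator scores."""
    expr, emb, truth = fr.simulate_branching(seed=1)
    ns = analyze_branching(expr, emb, truth)
    root = ns.roots["A"]
    trajs = {}
    for term, lab in ns.terminals.items():
        res = fr.trajectories_between(ns.sim_traj, ns.assign, ns.expr, [(root, lab)])
        assert res[0].trajectory is not None, res[0].error
        trajs[term] = res[0].trajectory
    traj = trajs["B"]
    smoothed = fr.neighborhood_smooth(ns.expr, ns.sim_traj, traj)
    pseudo = np.array([traj.pseudotime[c] for c in traj.cells])
    ranking = fr.rank_genes(smoothed, pseudo)
    regs = fr.regulator_list(truth).intersect(ns.expr.gene_ids)
    mi = fr.mutual_information_matrix(ns.expr, regs)
    net = fr.clr_zscores(mi)
    scores = fr.score_regulators(net, ranking)
    ns.root = root
    ns.trajectories = trajs
    ns.smoothed = smoothed
    ns.pseudotime = pseudo
    ns.ranking = ranking
    ns.grn = net
    ns.scores = scores
    return ns


@pytest.fixture(scope="session")
def convergence_run():
    """Two roots converging on one sink (450 cells, 300 genes, seed 7)."""
    expr, emb, truth = fr.simulate_branching(
        n_cells=450, n_genes=300, topology="convergence", seed=7
    )
    ns = analyze_branching(expr, emb, truth)
    sink = ns.terminals["C"]
    ns.results = {}
    for rb, root_lab in ns.roots.items():
        res = fr.trajectories_between(ns.sim_traj, ns.assign, ns.expr, [(root_lab, sink)])
        ns.results[rb] = res[0]
    return ns
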