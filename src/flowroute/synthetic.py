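"""Synthetic branching single-cell data with known ground truth.

The generator emulates the features of a differentiation snapshot that the
pipeline relies on: a continuum of cells along a branching (or converging)
topology, branch-restricted marker genes with sigmoid activation or
deactivation kinetics, planted master regulators that activate earlier than
their target genes and share noise with them (so regulator-target coupling
is detectable as mutual information), additive Gaussian noise, and
expression-dependent dropout. Values are log-scale abundances by
construction. Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io import Embedding, ExpressionMatrix, FlowRouteError, RegulatorList

TOPOLOGIES = ("linear", "bifurcation", "convergence")


@dataclass
class Branch:
    name: str
    t_start: float
    t_end: float
    lineage: tuple  # branch names from a root down to (and including) this branch
    start_xy: tuple
    end_xy: tuple

    @property
    def span(self) -> float:
        return self.t_end - self.t_start

    def xy(self, t: float) -> tuple:
        f = (t - self.t_start) / self.span
        return (
            self.start_xy[0] + f * (self.end_xy[0] - self.start_xy[0]),
            self.start_xy[1] + f * (self.end_xy[1] - self.start_xy[1]),
        )


def _topology(name: str) -> tuple[list[Branch], list[str], list[str]]:
    """Returns (branches, root branch names, terminal branch names)."""
    if name == "linear":
        branches = [Branch("A", 0.0, 1.0, ("A",), (0.0, 0.0), (10.0, 0.0))]
        return branches, ["A"], ["A"]
    if name == "bifurcation":
        s = 5.0 / np.sqrt(2.0)
        branches = [
            Branch("A", 0.0, 0.5, ("A",), (0.0, 0.0), (5.0, 0.0)),
            Branch("B", 0.5, 1.0, ("A", "B"), (5.0, 0.0), (5.0 + s, s)),
            Branch("C", 0.5, 1.0, ("A", "C"), (5.0, 0.0), (5.0 + s, -s)),
        ]
        return branches, ["A"], ["B", "C"]
    if name == "convergence":
        branches = [
            Branch("A", 0.0, 0.5, ("A",), (0.0, 3.0), (5.0, 0.0)),
            Branch("B", 0.0, 0.5, ("B",), (0.0, -3.0), (5.0, 0.0)),
            Branch("C", 0.5, 1.0, ("C",), (5.0, 0.0), (10.0, 0.0)),
        ]
        return branches, ["A", "B"], ["C"]
    raise FlowRouteError(f"unknown topology {name!r}; choose from {TOPOLOGIES}")


@dataclass
class GroundTruth:
    """Planted structure of one simulation run."""

    branch_labels: dict[str, str]
    segment_labels: dict[str, str]  # branch split at its pseudotime midpoint
    true_pseudotime: dict[str, float]
    marker_map: dict[str, dict[str, list[str]]]  # terminal branch -> {"up": [...], "down": [...]}
    planted_grn: dict[str, dict]  # regulator -> {"targets": [...], "sign": +1, "branch": ...}
    master_regulators: dict[str, str]  # terminal branch -> regulator gene
    root_branches: list[str]
    terminal_branches: list[str]
    lineages: dict[str, tuple] = field(default_factory=dict)
    inert_regulators: list[str] = field(default_factory=list)
    seed: int = 0

    def lineage_cells(self, terminal: str) -> set:
        """Cells on any branch of the lineage leading to ``terminal`` (for a
        convergent sink, cells of the sink and of every root)."""
        branches = set(self.lineages.get(terminal, (terminal,)))
        if terminal in self.terminal_branches and not set(self.root_branches) & branches:
            branches |= set(self.root_branches)
        return {c for c, b in self.branch_labels.items() if b in branches}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_branching(
    n_cells: int = 600,
    n_genes: int = 500,
    topology: str = "bifurcation",
    noise_sd: float = 0.25,
    dropout_rate: float = 0.1,
    seed: int = 0,
    n_targets_per_branch: int = 20,
    n_decoy_targets: int = 2,
    n_extra_up: int = 7,
    n_down_markers: int = 15,
    n_inert_regulators: int = 20,
    embedding_mode: str = "layout",
) -> tuple[ExpressionMatrix, Embedding, GroundTruth]:
    """Simulate a branching differentiation snapshot.

    Cells are allocated uniformly at random among branches and uniformly in
    pseudotime within their branch. Per terminal branch the gene panel
    contains one master regulator (early sigmoid) driving
    ``n_targets_per_branch`` up-targets (later sigmoids sharing the
    regulator's noise), one decoy regulator driving ``n_decoy_targets``,
    and ``n_extra_up`` free up-markers; ``n_down_markers`` genes decline
    from the root in every cell; the remainder are noise genes, of which
    ``n_inert_regulators`` are listed as regulators with no planted targets.
    The embedding is the 2-D branch layout plus Gaussian jitter
    (sd 0.30 on branches of length ~5-7), or a 2-component PCA of the
    expression when ``embedding_mode="pca"``.
    """
    if not 0 <= dropout_rate < 1:
        raise FlowRouteError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
    branches, roots, terminals = _topology(topology)
    per_branch = (
        1 + n_targets_per_branch + 1 + n_decoy_targets + n_extra_up
    )  # master + targets + decoy + decoy targets + extra up
    n_structured = per_branch * len(terminals) + n_down_markers + n_inert_regulators
    if n_genes < n_structured + 5:
        raise FlowRouteError(
            f"n_genes={n_genes} too small for the planted structure ({n_structured} genes)"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_cells)))
    cell_ids = [f"C{i + 1:0{width}d}" for i in range(n_cells)]

    branch_idx = rng.integers(0, len(branches), size=n_cells)
    t_local = rng.uniform(0.0, 1.0, size=n_cells)
    t_global = np.array(
        [branches[bi].t_start + u * branches[bi].span for bi, u in zip(branch_idx, t_local)]
    )
    branch_names = [branches[bi].name for bi in branch_idx]
    lineage_of = {b.name: b.lineage for b in branches}
    # terminal lineages; a convergent sink inherits every root
    term_lineages = {}
    for term in terminals:
        lin = set(lineage_of[term])
        if not lin & set(roots):
            lin |= set(roots)
        term_lineages[term] = lin

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    marker_map: dict[str, dict[str, list[str]]] = {t: {"up": [], "down": []} for t in terminals}
    planted_grn: dict[str, dict] = {}
    master_regulators: dict[str, str] = {}

    def on_lineage(term: str) -> np.ndarray:
        lin = term_lineages[term]
        return np.array([b in lin for b in branch_names])

    def up_gene(mask: np.ndarray, mid: float, steep: float, amp: float) -> np.ndarray:
        base = amp * _sigmoid((t_global - mid) / steep)
        return np.where(mask, base, 0.0)

    for term in terminals:
        b = next(br for br in branches if br.name == term)
        mask = on_lineage(term)
        steep = 0.08
        # master regulator: activates near the branch start, before its targets
        reg_mid = b.t_start + 0.10 * b.span
        reg_name = f"REG_{term}"
        reg_amp = float(rng.uniform(2.5, 3.5))
        reg_clean = up_gene(mask, reg_mid, steep, reg_amp)
        reg_noise = rng.normal(0.0, noise_sd, size=n_cells)
        gene_ids.append(reg_name)
        gene_rows.append(reg_clean + reg_noise)
        master_regulators[term] = reg_name
        marker_map[term]["up"].append(reg_name)

        targets = []
        for ti in range(n_targets_per_branch):
            mid = reg_mid + float(rng.uniform(0.15, 0.7)) * b.span
            amp = float(rng.uniform(2.0, 4.0))
            name = f"TG_{term}_{ti + 1:02d}"
            coupled = 0.6 * reg_noise  # shared noise marks the regulatory link
            gene_ids.append(name)
            gene_rows.append(up_gene(mask, mid, steep, amp) + coupled)
            targets.append(name)
            marker_map[term]["up"].append(name)
        planted_grn[reg_name] = {"targets": targets, "sign": 1, "branch": term}

        decoy_name = f"DREG_{term}"
        decoy_mid = b.t_start + 0.12 * b.span
        decoy_amp = float(rng.uniform(2.5, 3.5))
        decoy_clean = up_gene(mask, decoy_mid, steep, decoy_amp)
        decoy_noise = rng.normal(0.0, noise_sd, size=n_cells)
        gene_ids.append(decoy_name)
        gene_rows.append(decoy_clean + decoy_noise)
        marker_map[term]["up"].append(decoy_name)
        decoy_targets = []
        for ti in range(n_decoy_targets):
            mid = decoy_mid + float(rng.uniform(0.15, 0.7)) * b.span
            amp = float(rng.uniform(2.0, 4.0))
            name = f"DTG_{term}_{ti + 1}"
            gene_ids.append(name)
            gene_rows.append(up_gene(mask, mid, steep, amp) + 0.6 * decoy_noise)
            decoy_targets.append(name)
            marker_map[term]["up"].append(name)
        planted_grn[decoy_name] = {"targets": decoy_targets, "sign": 1, "branch": term}

        for mi in range(n_extra_up):
            mid = b.t_start + float(rng.uniform(0.2, 0.8)) * b.span
            amp = float(rng.uniform(2.0, 4.0))
            name = f"MK_{term}_UP{mi + 1:02d}"
            gene_ids.append(name)
            gene_rows.append(up_gene(mask, mid, steep, amp))
            marker_map[term]["up"].append(name)

    for di in range(n_down_markers):
        mid = float(rng.uniform(0.25, 0.5))
        amp = float(rng.uniform(2.0, 4.0))
        name = f"MK_DOWN{di + 1:02d}"
        gene_ids.append(name)
        gene_rows.append(amp * (1.0 - _sigmoid((t_global - mid) / 0.08)))
        for term in terminals:
            marker_map[term]["down"].append(name)

    inert_regs = []
    for ri in range(n_inert_regulators):
        name = f"REGN{ri + 1:02d}"
        base = float(rng.uniform(0.5, 2.0))
        gene_ids.append(name)
        gene_rows.append(np.full(n_cells, base))
        inert_regs.append(name)

    n_noise = n_genes - len(gene_ids)
    for ni in range(n_noise):
        base = float(rng.uniform(0.5, 2.0))
        gene_ids.append(f"NS{ni + 1:04d}")
        gene_rows.append(np.full(n_cells, base))

    values = np.vstack(gene_rows)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    if dropout_rate > 0:
        p_drop = dropout_rate * np.exp(-values)
        values = np.where(rng.uniform(size=values.shape) < p_drop, 0.0, values)

    expr = ExpressionMatrix(values, gene_ids, cell_ids)

    if embedding_mode == "layout":
        coords = np.array(
            [branches[bi].xy(t) for bi, t in zip(branch_idx, t_global)], dtype=float
        )
        coords = coords + rng.normal(0.0, 0.30, size=coords.shape)
    elif embedding_mode == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(values.T)
    else:
        raise FlowRouteError(f"unknown embedding_mode {embedding_mode!r}")
    emb = Embedding(coords, cell_ids)

    seg_labels = {}
    for cell, bi, t in zip(cell_ids, branch_idx, t_global):
        b = branches[bi]
        half = "1" if t < b.t_start + 0.5 * b.span else "2"
        seg_labels[cell] = f"{b.name}{half}"
    truth = GroundTruth(
        branch_labels=dict(zip(cell_ids, branch_names)),
        segment_labels=seg_labels,
        true_pseudotime=dict(zip(cell_ids, t_global.tolist())),
        marker_map=marker_map,
        planted_grn=planted_grn,
        master_regulators=master_regulators,
        root_branches=roots,
        terminal_branches=terminals,
        lineages={t: tuple(sorted(term_lineages[t])) for t in terminals},
        inert_regulators=inert_regs,
        seed=seed,
    )
    return expr, emb, truth


def regulator_list(truth: GroundTruth) -> RegulatorList:
    """The planted regulators plus the inert decoys carried in the gene panel."""
    return RegulatorList(set(truth.planted_grn) | set(truth.inert_regulators))


def simulate_clusters(
    n_cells: int = 300,
    n_clusters: int = 4,
    separation: float = 10.0,
    spread: float = 1.0,
    seed: int = 0,
) -> tuple[Embedding, dict[str, int]]:
    """Well-separated Gaussian blobs in 2-D, for community-detection checks.

    Cluster centers sit on a circle of radius ``separation``; points are
    isotropic Gaussian with sd ``spread``."""
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_cells)))
    cell_ids = [f"C{i + 1:0{width}d}" for i in range(n_cells)]
    labels = rng.integers(0, n_clusters, size=n_cells)
    angles = 2 * np.pi * np.arange(n_clusters) / n_clusters
    centers = separation * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = centers[labels] + rng.normal(0.0, spread, size=(n_cells, 2))
    return Embedding(coords, cell_ids), {c: int(l) + 1 for c, l in zip(cell_ids, labels)}


def simulate_linear_grn(
    n_regulators: int = 5,
    targets_per_regulator: int = 4,
    n_other_genes: int = 75,
    n_cells: int = 400,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, RegulatorList, set]:
    """A flat regulator->target network with linear activations plus noise:
    each regulator's expression varies across cells and each of its targets
    is a scaled copy plus independent Gaussian noise. Returns the expression
    matrix, the regulator list and the planted edge set."""
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_cells)))
    cell_ids = [f"C{i + 1:0{width}d}" for i in range(n_cells)]
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    edges = set()
    regs = set()
    for ri in range(n_regulators):
        reg = f"R{ri + 1:02d}"
        profile = np.abs(rng.normal(0.0, 1.5, size=n_cells))
        gene_ids.append(reg)
        rows.append(profile)
        regs.add(reg)
        for ti in range(targets_per_regulator):
            tgt = f"R{ri + 1:02d}_T{ti + 1}"
            slope = float(rng.uniform(0.6, 1.4))
            gene_ids.append(tgt)
            rows.append(slope * profile + rng.normal(0.0, noise_sd, size=n_cells))
            edges.add((reg, tgt))
    for gi in range(n_other_genes):
        gene_ids.append(f"N{gi + 1:03d}")
        rows.append(np.abs(rng.normal(0.0, 1.0, size=n_cells)))
    values = np.clip(np.vstack(rows), 0.0, None)
    return ExpressionMatrix(values, gene_ids, cell_ids), RegulatorList(regs), edges
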