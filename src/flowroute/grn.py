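"""CLR-style gene regulatory network reconstruction and regulator scoring.

Cell-to-cell heterogeneity in single-cell profiles acts as a natural
perturbation set, so regulator-target dependencies can be read out as
mutual information between expression profiles across cells. Each
regulator-gene MI value is corrected against the background MI
distributions of both genes (CLR z-scores), and regulators of a trajectory
are ranked by a score combining their own trajectory correlation, the mean
correlation of their induced targets and the number of such targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import GeneRanking
from .io import ExpressionMatrix, FlowRouteError, RegulatorList


@dataclass
class GRN:
    """Edge list of (regulator, target) with mutual information and CLR
    z-score; only edges at or above the z threshold are retained."""

    edges: pd.DataFrame  # columns: regulator, target, mi, zscore
    regulators: RegulatorList
    z_threshold: float = 3.0

    def targets_of(self, regulator: str) -> list[str]:
        return self.edges.loc[self.edges["regulator"] == regulator, "target"].tolist()

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class RegulatorScore:
    """Score = |c| * m * n for one regulator along one trajectory, where c
    is the regulator's Spearman rho with the trajectory, m the mean rho of
    its induced targets and n their count. ``mechanism`` records whether the
    regulator itself rises (induction) or falls (de-repression) while its
    targets rise."""

    regulator: str
    c: float
    m: float
    n: int
    score: float
    mechanism: str  # "induction" | "de-repression"
    targets: list[str] = field(default_factory=list)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(x, edges)


def _entropy_from_labels(labels: np.ndarray, bins: int) -> float:
    counts = np.bincount(labels, minlength=bins)
    p = counts[counts > 0] / labels.size
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(
    expr: ExpressionMatrix, regs: RegulatorList, bins: int = 10
) -> pd.DataFrame:
    """Plug-in mutual information (nats) between every regulator and every
    gene, with equal-frequency binning (default 10 bins). Constant genes
    have MI 0 against everything. Returns regulators x genes."""
    regs = regs.intersect(expr.gene_ids)
    if len(regs) == 0:
        raise FlowRouteError("no regulators present in the expression matrix")
    if expr.n_cells < 50:
        warnings.warn(
            f"only {expr.n_cells} cells; MI estimates are unreliable below ~50 cells",
            stacklevel=2,
        )
    n = expr.n_cells
    labels = np.empty((expr.n_genes, n), dtype=np.intp)
    constant = np.zeros(expr.n_genes, dtype=bool)
    for i in range(expr.n_genes):
        x = expr.values[i]
        if np.ptp(x) == 0:
            constant[i] = True
            labels[i] = 0
        else:
            labels[i] = _equal_frequency_bins(x, bins)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    reg_names = sorted(regs.genes)
    mi = np.zeros((len(reg_names), expr.n_genes))
    log_n = np.log(n)
    for ri, reg in enumerate(reg_names):
        i = gene_index[reg]
        if constant[i]:
            continue
        li = labels[i]
        for j in range(expr.n_genes):
            if constant[j]:
                continue
            joint = np.bincount(li * bins + labels[j], minlength=bins * bins)
            nz = joint[joint > 0]
            h_joint = -(nz / n * (np.log(nz) - log_n)).sum()
            hx = _entropy_from_labels(li, bins)
            hy = _entropy_from_labels(labels[j], bins)
            mi[ri, j] = max(0.0, hx + hy - h_joint)
    return pd.DataFrame(mi, index=reg_names, columns=expr.gene_ids)


def clr_zscores(
    mi: pd.DataFrame, regulators: RegulatorList | None = None, z_threshold: float = 3.0
) -> GRN:
    """Context-likelihood-of-relatedness scores: each MI value is z-scored
    against its regulator's row background and its target's column
    background (negative z clipped to 0) and combined as
    sqrt(z_row^2 + z_col^2). Edges with zscore >= ``z_threshold`` are kept;
    self-edges are dropped. Zero-variance backgrounds contribute 0."""
    m = mi.to_numpy(dtype=float)
    row_mean = m.mean(axis=1, keepdims=True)
    row_sd = m.std(axis=1, keepdims=True)
    col_mean = m.mean(axis=0, keepdims=True)
    col_sd = m.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = np.where(row_sd > 0, (m - row_mean) / row_sd, 0.0)
        zc = np.where(col_sd > 0, (m - col_mean) / col_sd, 0.0)
    zr = np.clip(zr, 0, None)
    zc = np.clip(zc, 0, None)
    z = np.sqrt(zr**2 + zc**2)
    rows = []
    for ri, reg in enumerate(mi.index):
        for ci, gene in enumerate(mi.columns):
            if gene == reg:
                continue
            if z[ri, ci] >= z_threshold:
                rows.append((reg, gene, float(m[ri, ci]), float(z[ri, ci])))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi", "zscore"])
    return GRN(
        edges=edges,
        regulators=regulators if regulators is not None else RegulatorList(set(mi.index)),
        z_threshold=z_threshold,
    )


def score_regulators(
    grn: GRN, ranking: GeneRanking, direction: str = "up"
) -> list[RegulatorScore]:
    """Rank regulators of a trajectory by score = |c| * m * n over their
    targets classified ``direction`` (default "up") in the gene ranking.
    Mechanism is induction when the regulator itself is positively
    correlated with the trajectory, de-repression when negatively.
    Regulators absent from the ranking are skipped with a warning."""
    if grn.n_edges == 0:
        raise FlowRouteError("GRN has no edges")
    if direction != "up":
        raise FlowRouteError(f"unsupported direction: {direction}")
    scores = []
    for reg in sorted(set(grn.edges["regulator"])):
        if reg not in ranking.rho or not np.isfinite(ranking.rho[reg]):
            warnings.warn(f"regulator {reg} absent from ranking; skipped", stacklevel=2)
            continue
        c = ranking.rho[reg]
        targets = [
            t
            for t in grn.targets_of(reg)
            if ranking.classes.get(t) == direction and np.isfinite(ranking.rho.get(t, float("nan")))
        ]
        n = len(targets)
        m = float(np.mean([ranking.rho[t] for t in targets])) if n else 0.0
        scores.append(
            RegulatorScore(
                regulator=reg,
                c=float(c),
                m=m,
                n=n,
                score=abs(c) * m * n,
                mechanism="induction" if c > 0 else "de-repression",
                targets=targets,
            )
        )
    scores.sort(key=lambda s: (-s.score, s.regulator))
    return scores


def regulator_subnetwork(grn: GRN, regulators, ranking: GeneRanking | None = None) -> GRN:
    """Induced sub-network of the named regulators: their outgoing edges
    plus any edges among the selected regulators and their targets."""
    regulators = set(regulators)
    if not regulators:
        raise FlowRouteError("empty regulator selection")
    known = set(grn.edges["regulator"])
    unknown = regulators - known
    if unknown:
        raise FlowRouteError(f"regulators not in GRN: {sorted(unknown)[:5]}")
    direct = grn.edges[grn.edges["regulator"].isin(regulators)]
    nodes = regulators | set(direct["target"])
    mask = grn.edges["regulator"].isin(nodes) & grn.edges["target"].isin(nodes)
    edges = grn.edges[mask].reset_index(drop=True)
    return GRN(edges=edges, regulators=RegulatorList(regulators), z_threshold=grn.z_threshold)
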