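"""Gene-expression dynamics along a trajectory: neighborhood smoothing,
correlation-based gene ranking, spline kinetic trends, trend clustering and
PCA-loading gene selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .flownet import Trajectory
from .graph import CellGraph
from .io import ExpressionMatrix, FlowRouteError

GRID_SIZE = 500


@dataclass
class KineticTrend:
    """Per-gene smoothed expression curve over a uniform pseudotime grid.

    ``rescaled`` maps the smooth curve onto [0, 1]; it is None when the
    smooth curve is constant (zero range).
    """

    gene: str
    grid: np.ndarray
    raw: np.ndarray
    smooth: np.ndarray
    rescaled: np.ndarray | None

    @property
    def is_constant(self) -> bool:
        return self.rescaled is None


@dataclass
class GeneRanking:
    """Spearman rho of each gene against trajectory progression, with
    up/down classes assigned by empirical quantiles of the rho distribution."""

    rho: dict[str, float]  # NaN for constant genes
    classes: dict[str, str]  # "up" | "down" | "none"
    upper_q: float
    lower_q: float
    upper_threshold: float
    lower_threshold: float

    def genes_in_class(self, cls: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == cls]


@dataclass
class TrendClusters:
    assignment: dict[str, int]
    medoids: dict[int, str]
    n_clusters: int


def neighborhood_smooth(
    expr: ExpressionMatrix, graph: CellGraph, traj: Trajectory
) -> pd.DataFrame:
    """Replace each path cell's expression by the mean over the cell and its
    graph neighbors, borrowing strength from the local kNN topology to
    mitigate drop-outs. Returns genes x path-cells."""
    cell_index = {c: j for j, c in enumerate(expr.cell_ids)}
    g = graph.graph.to_undirected() if graph.graph.is_directed() else graph.graph
    out = np.empty((expr.n_genes, len(traj.cells)))
    for j, cell in enumerate(traj.cells):
        if cell not in g:
            raise FlowRouteError(f"path cell {cell} absent from graph")
        if cell not in cell_index:
            raise FlowRouteError(f"path cell {cell} absent from expression matrix")
        pool = [cell, *g.neighbors(cell)]
        cols = [cell_index[c] for c in pool if c in cell_index]
        out[:, j] = expr.values[:, cols].mean(axis=1)
    return pd.DataFrame(out, index=expr.gene_ids, columns=traj.cells)


def rank_genes(
    expr_on_path: pd.DataFrame,
    pseudotime: np.ndarray,
    upper_q: float = 0.85,
    lower_q: float = 0.15,
) -> GeneRanking:
    """Spearman-correlate each gene with pseudotime and classify genes above
    the upper rho quantile as "up" (induced along the trajectory) and below
    the lower quantile as "down". Constant genes get class "none" and are
    excluded from the quantile computation."""
    pseudotime = np.asarray(pseudotime, dtype=float)
    if expr_on_path.shape[1] < 3:
        raise FlowRouteError("need at least 3 path cells to rank genes")
    if expr_on_path.shape[1] != len(pseudotime):
        raise FlowRouteError("pseudotime length does not match path cells")
    if np.any(np.diff(pseudotime) <= 0):
        raise FlowRouteError("pseudotime must be strictly increasing")
    values = expr_on_path.to_numpy()
    rho: dict[str, float] = {}
    for gene, series in zip(expr_on_path.index, values):
        if np.ptp(series) == 0:
            rho[gene] = float("nan")
        else:
            rho[gene] = float(spearmanr(series, pseudotime).statistic)
    finite = np.array([r for r in rho.values() if np.isfinite(r)])
    if finite.size == 0:
        raise FlowRouteError("all genes constant along the path")
    hi = float(np.quantile(finite, upper_q))
    lo = float(np.quantile(finite, lower_q))
    classes = {}
    for gene, r in rho.items():
        if not np.isfinite(r):
            classes[gene] = "none"
        elif r >= hi:
            classes[gene] = "up"
        elif r <= lo:
            classes[gene] = "down"
        else:
            classes[gene] = "none"
    return GeneRanking(
        rho=rho,
        classes=classes,
        upper_q=upper_q,
        lower_q=lower_q,
        upper_threshold=hi,
        lower_threshold=lo,
    )


def fit_trend(
    raw,
    pseudotime,
    gene: str = "",
    lam: float | None = None,
    grid_size: int = GRID_SIZE,
) -> KineticTrend:
    """Fit a cubic smoothing spline to one gene's expression along
    pseudotime and evaluate it on a uniform grid over [0, 1].

    The smoothing parameter is chosen by generalized cross-validation unless
    ``lam`` overrides it. With exactly 4 points (the minimum) an
    interpolating cubic spline is used, since GCV needs 5+ points. The
    rescaled curve maps smooth onto [0, 1]; it is None for constant curves.
    """
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if raw.size < 4:
        raise FlowRouteError(f"need at least 4 points to fit a trend, got {raw.size}")
    if raw.size != t.size:
        raise FlowRouteError("series and pseudotime lengths differ")
    if np.any(np.diff(t) <= 0):
        raise FlowRouteError("pseudotime must be strictly increasing")
    grid = np.linspace(t[0], t[-1], grid_size)
    if np.ptp(raw) == 0:
        smooth = np.full(grid_size, raw[0])
        return KineticTrend(gene=gene, grid=grid, raw=raw, smooth=smooth, rescaled=None)
    if raw.size < 5 and lam is None:
        spline = CubicSpline(t, raw)
    else:
        spline = make_smoothing_spline(t, raw, lam=lam)
    smooth = np.asarray(spline(grid), dtype=float)
    rng = np.ptp(smooth)
    rescaled = (smooth - smooth.min()) / rng if rng > 0 else None
    return KineticTrend(gene=gene, grid=grid, raw=raw, smooth=smooth, rescaled=rescaled)


def trend_distance(x: KineticTrend, y: KineticTrend) -> float:
    """Kinetic dissimilarity d(x, y) = 1 - pearson(x.smooth, y.smooth) / 2,
    mapping perfectly correlated curves to 0.5 and mirrored ones to 1.5."""
    if x.grid.shape != y.grid.shape or not np.allclose(x.grid, y.grid):
        raise FlowRouteError("trends are on different grids")
    if np.ptp(x.smooth) == 0 or np.ptp(y.smooth) == 0:
        raise FlowRouteError("trend distance undefined for constant curves")
    c = float(np.corrcoef(x.smooth, y.smooth)[0, 1])
    return 1.0 - c / 2.0


def _pam(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """Plain PAM: seeded random build, then best-improvement swaps."""
    n = dist.shape[0]
    medoids = list(rng.choice(n, size=k, replace=False))

    def total_cost(meds):
        return dist[:, meds].min(axis=1).sum()

    cost = total_cost(medoids)
    for _ in range(max_iter):
        best_delta = 0.0
        best_swap = None
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c = total_cost(cand)
                if c < cost + best_delta - 1e-12:
                    best_delta = c - cost
                    best_swap = (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        cost += best_delta
    labels = np.asarray(dist[:, medoids].argmin(axis=1))
    return medoids, labels


def cluster_trends(
    trends: list[KineticTrend], n_clusters: int, seed: int = 0
) -> TrendClusters:
    """K-medoid (PAM) clustering of kinetic trends.

    Smooth curves are log(1 + .)-transformed and z-scored per gene, then
    clustered on the pairwise distance d = 1 - pearson/2. Deterministic for
    a given seed."""
    genes = [t.gene for t in trends]
    if n_clusters < 2 or n_clusters >= len(trends):
        raise FlowRouteError(
            f"n_clusters must be in [2, n_genes); got {n_clusters} for {len(trends)} genes"
        )
    curves = np.array([np.log1p(np.clip(t.smooth, 0, None)) for t in trends])
    sd = curves.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        flat = [genes[i] for i in np.where(sd[:, 0] == 0)[0]]
        raise FlowRouteError(f"constant trends cannot be clustered: {flat[:5]}")
    z = (curves - curves.mean(axis=1, keepdims=True)) / sd
    corr = np.corrcoef(z)
    dist = 1.0 - corr / 2.0
    np.fill_diagonal(dist, 0.0)
    rng = np.random.default_rng(seed)
    medoid_idx, labels = _pam(dist, n_clusters, rng)
    assignment = {g: int(lab) + 1 for g, lab in zip(genes, labels)}
    medoids = {int(ci) + 1: genes[mi] for ci, mi in enumerate(medoid_idx)}
    return TrendClusters(assignment=assignment, medoids=medoids, n_clusters=n_clusters)


def select_trajectory_genes(
    expr: ExpressionMatrix, n_pcs: int = 5, loading_q: float = 0.975
) -> list[str]:
    """Select genes carrying the major axes of variation: the union over the
    first ``n_pcs`` principal components of genes whose absolute loading
    exceeds the per-component ``loading_q`` quantile."""
    if expr.n_cells <= n_pcs or expr.n_genes <= n_pcs:
        raise FlowRouteError(f"matrix too small for {n_pcs} principal components")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pca.fit(expr.values.T)  # samples = cells, features = genes
    loadings = pca.components_  # n_pcs x n_genes
    selected: set[int] = set()
    for comp in np.abs(loadings):
        thr = np.quantile(comp, loading_q)
        selected.update(np.where(comp >= thr)[0])
    return [expr.gene_ids[i] for i in sorted(selected)]
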