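"""Trajectory-quality metrics: lag-1 autocorrelation of marker kinetics and
counts of genes significantly correlated with a trajectory.

A well-reconstructed ordering yields smooth expression dynamics, so marker
autocorrelation discriminates good orderings from scrambled ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import rank_genes
from .io import FlowRouteError


@dataclass
class QualityReport:
    n_up: int
    n_down: int
    marker_autocorr: dict[str, float]  # NaN for constant markers

    @property
    def mean_marker_autocorr(self) -> float:
        vals = [v for v in self.marker_autocorr.values() if np.isfinite(v)]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def lag_autocorrelation(x, lag: int = 1) -> float:
    """Sample autocorrelation r_t = c_t / c_0 with the 1/n-normalized
    autocovariance c_t = (1/n) * sum_s (x_{s+t} - xbar)(x_s - xbar), the sum
    running over the overlap of the series with its lagged copy."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < lag + 2:
        raise FlowRouteError(f"series of length {n} too short for lag {lag}")
    xbar = x.mean()
    d = x - xbar
    c0 = (d * d).sum() / n
    if c0 == 0:
        raise FlowRouteError("autocorrelation undefined for a constant series")
    # s from max(1, -t) to min(n - t, n) in 1-based indexing
    ct = (d[lag:] * d[: n - lag]).sum() / n
    return float(ct / c0)


def quality_report(
    expr_on_path: pd.DataFrame,
    pseudotime,
    markers: list[str],
    upper_q: float = 0.85,
    lower_q: float = 0.15,
) -> QualityReport:
    """Count up/down genes under the rho-quantile rule and compute each
    marker's lag-1 autocorrelation along the ordering. Constant markers are
    reported as NaN and excluded from aggregates."""
    missing = [m for m in markers if m not in expr_on_path.index]
    if missing:
        raise FlowRouteError(f"markers absent from expression: {missing[:5]}")
    ranking = rank_genes(expr_on_path, pseudotime, upper_q=upper_q, lower_q=lower_q)
    n_up = len(ranking.genes_in_class("up"))
    n_down = len(ranking.genes_in_class("down"))
    autocorr = {}
    for m in markers:
        series = expr_on_path.loc[m].to_numpy()
        if np.ptp(series) == 0:
            autocorr[m] = float("nan")
        else:
            autocorr[m] = lag_autocorrelation(series, lag=1)
    return QualityReport(n_up=n_up, n_down=n_down, marker_autocorr=autocorr)
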