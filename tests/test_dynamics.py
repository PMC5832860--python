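import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import flowroute as fr
from flowroute.io import FlowRouteError


def _toy_trajectory(cells):
    m = len(cells)
    return fr.Trajectory(
        cells=list(cells),
        flow=1.0,
        cost=0.0,
        length=m - 1,
        pseudotime={c: i / (m - 1) for i, c in enumerate(cells)},
    )


class TestNeighborhoodSmooth:
    def _graph(self, edges, nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_edge(u, v, weight=0.5)
        return fr.CellGraph(graph=g, kind="similarity", k=1)

    def test_isolated_cell_unchanged(self):
        expr = fr.ExpressionMatrix(np.array([[1.0, 2.0, 5.0]]), ["g"], ["a", "b", "c"])
        cg = self._graph([("b", "c")], ["a", "b", "c"])
        out = fr.neighborhood_smooth(expr, cg, _toy_trajectory(["a", "b"]))
        assert out.loc["g", "a"] == 1.0

    def test_mean_over_neighbors(self):
        # cell 'a' expresses 3, both neighbors 0 -> smoothed to 1
        expr = fr.ExpressionMatrix(np.array([[3.0, 0.0, 0.0]]), ["g"], ["a", "b", "c"])
        cg = self._graph([("a", "b"), ("a", "c")], ["a", "b", "c"])
        out = fr.neighborhood_smooth(expr, cg, _toy_trajectory(["a", "b"]))
        assert out.loc["g", "a"] == pytest.approx(1.0)

    def test_constant_gene_unchanged(self):
        expr = fr.ExpressionMatrix(np.full((1, 3), 2.0), ["g"], ["a", "b", "c"])
        cg = self._graph([("a", "b"), ("b", "c")], ["a", "b", "c"])
        out = fr.neighborhood_smooth(expr, cg, _toy_trajectory(["a", "b", "c"]))
        assert (out.loc["g"] == 2.0).all()

    def test_missing_cell_errors(self):
        expr = fr.ExpressionMatrix(np.ones((1, 2)), ["g"], ["a", "b"])
        cg = self._graph([("a", "b")], ["a", "b"])
        with pytest.raises(FlowRouteError, match="absent"):
            fr.neighborhood_smooth(expr, cg, _toy_trajectory(["a", "z"]))

    def test_variance_contraction(self):
        """Mean filtering over fixed neighborhoods never inflates the
        per-gene variance along the path."""
        rng = np.random.default_rng(3)
        n = 30
        cells = [f"c{i:02d}" for i in range(n)]
        expr = fr.ExpressionMatrix(
            np.abs(rng.normal(1, 0.6, size=(10, n))), [f"g{i}" for i in range(10)], cells
        )
        emb = fr.Embedding(rng.normal(size=(n, 2)), cells)
        cg = fr.jaccard_transform(fr.build_knn_graph(emb, 5))
        traj = _toy_trajectory(cells)
        out = fr.neighborhood_smooth(expr, cg, traj)
        raw_var = expr.values.var(axis=1)
        smooth_var = out.to_numpy().var(axis=1)
        assert (smooth_var <= raw_var + 1e-12).all()


class TestRankGenes:
    def _frame(self, rows, genes):
        return pd.DataFrame(rows, index=genes, columns=[f"c{i}" for i in range(len(rows[0]))])

    def test_perfect_monotone(self):
        df = self._frame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], ["up", "down"])
        r = fr.rank_genes(df, np.array([0.0, 0.5, 1.0]))
        assert r.rho["up"] == pytest.approx(1.0)
        assert r.rho["down"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_none(self):
        df = self._frame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "up"])
        r = fr.rank_genes(df, np.array([0.0, 0.5, 1.0]))
        assert np.isnan(r.rho["flat"]) and r.classes["flat"] == "none"

    def test_quantile_classification_fractions(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 40)
        rows = [rng.normal(size=40) for _ in range(100)]
        df = self._frame(rows, [f"g{i}" for i in range(100)])
        r = fr.rank_genes(df, t)
        n_up = len(r.genes_in_class("up"))
        n_down = len(r.genes_in_class("down"))
        assert 10 <= n_up <= 20 and 10 <= n_down <= 20  # ~15% each

    def test_planted_monotone_genes_rank_top(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 50)
        rows, genes = [], []
        for i in range(10):  # planted ramps
            rows.append(3 * t + rng.normal(0, 0.05, 50))
            genes.append(f"up{i}")
        for i in range(90):
            rows.append(rng.normal(1, 0.3, 50))
            genes.append(f"ns{i}")
        r = fr.rank_genes(self._frame(rows, genes), t)
        assert all(r.classes[f"up{i}"] == "up" for i in range(10))

    def test_invariant_to_monotone_pseudotime_transform(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0.01, 1, 25)
        df = self._frame([rng.normal(size=25) for _ in range(20)], [f"g{i}" for i in range(20)])
        r1 = fr.rank_genes(df, t)
        r2 = fr.rank_genes(df, np.log(t) + 5)
        for g in r1.rho:
            assert r1.rho[g] == pytest.approx(r2.rho[g], abs=1e-12)


class TestFitTrend:
    def test_linear_series_reproduced(self):
        t = np.linspace(0, 1, 30)
        trend = fr.fit_trend(2 * t + 1, t)
        assert np.abs(trend.smooth - (2 * trend.grid + 1)).max() < 1e-6
        assert trend.grid.size == 500

    def test_constant_series_flagged(self):
        t = np.linspace(0, 1, 10)
        trend = fr.fit_trend(np.ones(10), t)
        assert trend.is_constant and trend.rescaled is None
        assert (trend.smooth == 1.0).all()

    def test_smoothing_reduces_wiggles(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 40)
        raw = 1 / (1 + np.exp(-(t - 0.5) / 0.08)) + rng.normal(0, 0.3, 40)
        trend = fr.fit_trend(raw, t)
        sign_changes = lambda y: int(np.sum(np.diff(np.sign(np.diff(y))) != 0))
        assert sign_changes(trend.smooth) < sign_changes(raw)

    def test_rescaled_range(self):
        t = np.linspace(0, 1, 20)
        trend = fr.fit_trend(np.sin(2 * np.pi * t), t)
        assert trend.rescaled.min() == pytest.approx(0.0)
        assert trend.rescaled.max() == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(FlowRouteError, match="at least 4"):
            fr.fit_trend([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])

    def test_rescaling_idempotent_and_order_preserving(self):
        t = np.linspace(0, 1, 25)
        trend = fr.fit_trend(np.cos(3 * t) + 2, t)
        r = trend.rescaled
        r2 = (r - r.min()) / np.ptp(r)
        assert np.allclose(r, r2)
        assert np.array_equal(np.argsort(trend.smooth), np.argsort(r))


class TestTrendDistance:
    def _trend(self, y, t=None):
        t = np.linspace(0, 1, len(y)) if t is None else t
        return fr.fit_trend(np.asarray(y, dtype=float), t)

    def test_identity_distance_is_half(self):
        t = np.linspace(0, 1, 30)
        a = self._trend(np.sin(2 * np.pi * t))
        assert fr.trend_distance(a, a) == pytest.approx(0.5)

    def test_mirrored_distance(self):
        t = np.linspace(0, 1, 30)
        a = self._trend(np.sin(2 * np.pi * t))
        b = self._trend(-np.sin(2 * np.pi * t))
        assert fr.trend_distance(a, b) == pytest.approx(1.5, abs=1e-9)

    def test_orthogonal_sinusoids(self):
        t = np.linspace(0, 1, 200)
        a = self._trend(np.sin(2 * np.pi * t))
        b = self._trend(np.cos(2 * np.pi * t))
        assert fr.trend_distance(a, b) == pytest.approx(1.0, abs=0.02)

    def test_constant_curve_rejected(self):
        t = np.linspace(0, 1, 10)
        a = self._trend(np.sin(t))
        c = fr.fit_trend(np.ones(10), t)
        with pytest.raises(FlowRouteError, match="constant"):
            fr.trend_distance(a, c)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 20)
        a = self._trend(rng.normal(size=20))
        b = self._trend(rng.normal(size=20))
        d = fr.trend_distance(a, b)
        assert 0.5 - 1e-9 <= d <= 1.5 + 1e-9
        assert d == pytest.approx(fr.trend_distance(b, a), abs=1e-12)


class TestClusterTrends:
    def _family(self, base, n, rng, sd=0.15):
        t = np.linspace(0, 1, 40)
        return [
            fr.fit_trend(base(t) + rng.normal(0, sd, 40), t, gene=f"{base.__name__}_{i}")
            for i in range(n)
        ]

    def test_two_identical_families_split_perfectly(self):
        t = np.linspace(0, 1, 40)
        up = [fr.fit_trend(3 * t + 0.5, t, gene=f"u{i}") for i in range(5)]
        down = [fr.fit_trend(3 - 3 * t, t, gene=f"d{i}") for i in range(5)]
        cl = fr.cluster_trends(up + down, 2, seed=0)
        labels_up = {cl.assignment[f"u{i}"] for i in range(5)}
        labels_down = {cl.assignment[f"d{i}"] for i in range(5)}
        assert len(labels_up) == 1 and len(labels_down) == 1 and labels_up != labels_down

    def test_deterministic(self):
        rng = np.random.default_rng(7)

        def early(t):
            return 3 / (1 + np.exp(-(t - 0.3) / 0.05))

        trends = self._family(early, 10, rng)
        t = np.linspace(0, 1, 40)
        trends += [fr.fit_trend(rng.normal(1, 0.2, 40), t, gene=f"n{i}") for i in range(10)]
        a = fr.cluster_trends(trends, 3, seed=5)
        b = fr.cluster_trends(trends, 3, seed=5)
        assert a.assignment == b.assignment and a.medoids == b.medoids

    def test_three_archetype_recovery(self):
        rng = np.random.default_rng(11)

        def early(t):
            return 3 / (1 + np.exp(-(t - 0.3) / 0.05))

        def late_off(t):
            return 3 - 3 / (1 + np.exp(-(t - 0.6) / 0.05))

        def transient(t):
            return 3 * np.exp(-(((t - 0.5) / 0.15) ** 2))

        trends, labels = [], []
        for k, fam in enumerate((early, late_off, transient)):
            fam_trends = self._family(fam, 10, rng)
            trends.extend(fam_trends)
            labels.extend([k] * 10)
        cl = fr.cluster_trends(trends, 3, seed=0)
        found = [cl.assignment[t.gene] for t in trends]
        assert adjusted_rand_score(labels, found) >= 0.8

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 30)
        trends = [fr.fit_trend(rng.normal(1, 0.4, 30), t, gene=f"g{i}") for i in range(12)]
        cl = fr.cluster_trends(trends, 3, seed=1)
        for cid, medoid in cl.medoids.items():
            assert cl.assignment[medoid] == cid

    def test_invalid_cluster_count(self):
        t = np.linspace(0, 1, 30)
        trends = [fr.fit_trend(np.sin(t + i), t, gene=f"g{i}") for i in range(4)]
        with pytest.raises(FlowRouteError):
            fr.cluster_trends(trends, 1, seed=0)
        with pytest.raises(FlowRouteError):
            fr.cluster_trends(trends, 4, seed=0)


class TestSelectTrajectoryGenes:
    def test_dominant_variance_gene_selected(self):
        rng = np.random.default_rng(0)
        values = np.abs(rng.normal(1, 0.01, size=(30, 20)))
        values[4] = np.linspace(0, 10, 20)  # carries essentially all variance
        expr = fr.ExpressionMatrix(values, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(20)])
        assert "g4" in fr.select_trajectory_genes(expr)

    def test_iid_noise_selection_bounded(self):
        rng = np.random.default_rng(1)
        expr = fr.ExpressionMatrix(
            np.abs(rng.normal(1, 0.5, size=(1000, 60))),
            [f"g{i:04d}" for i in range(1000)],
            [f"c{i}" for i in range(60)],
        )
        selected = fr.select_trajectory_genes(expr, n_pcs=5, loading_q=0.975)
        assert 25 <= len(selected) <= 125

    def test_zero_quantile_selects_everything(self):
        rng = np.random.default_rng(2)
        expr = fr.ExpressionMatrix(
            np.abs(rng.normal(1, 0.5, size=(40, 15))),
            [f"g{i}" for i in range(40)],
            [f"c{i}" for i in range(15)],
        )
        assert len(fr.select_trajectory_genes(expr, loading_q=0.0)) == 40

    def test_too_small_matrix(self):
        expr = fr.ExpressionMatrix(np.ones((3, 3)), ["a", "b", "c"], ["x", "y", "z"])
        with pytest.raises(FlowRouteError):
            fr.select_trajectory_genes(expr, n_pcs=5)
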