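"""Thresholding and graph metrics against brute-force and networkx oracles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxeeg.graph import (
    AUCResult,
    BinaryGraph,
    DEFAULT_THRESHOLDS,
    GraphMetricCurve,
    degree,
    global_efficiency,
    metric_auc,
    nodal_clustering,
    nodal_efficiency,
    proportional_threshold,
    threshold_sweep,
    transitivity,
)

# --- independent brute-force oracles --------------------------------------


def floyd_warshall_distances(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_efficiency(adj):
    n = adj.shape[0]
    d = floyd_warshall_distances(adj)
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                e[i] += 1.0 / d[i, j]
    return e / (n - 1)


def brute_triples(adj):
    """Closed and connected triple counts by O(n^3) enumeration."""
    n = adj.shape[0]
    t = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for h in range(n):
                if j != i and h != i and h != j:
                    t[i] += adj[i, j] * adj[i, h] * adj[j, h]
    return t / 2.0


def random_graph(rng, n, p):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return BinaryGraph(a + a.T)


class TestHandValues:
    def test_complete_k4_efficiency_one(self):
        g = BinaryGraph(np.ones((4, 4), int) - np.eye(4, dtype=int))
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_path_of_three(self):
        a = np.zeros((3, 3), int)
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
        g = BinaryGraph(a)
        assert global_efficiency(g) == pytest.approx(5 / 6)
        np.testing.assert_allclose(nodal_efficiency(g), [0.75, 1.0, 0.75])

    def test_edgeless_graph_zero_efficiency(self):
        g = BinaryGraph(np.zeros((5, 5), int))
        assert global_efficiency(g) == 0.0

    def test_triangle_transitivity_one(self):
        g = BinaryGraph(np.ones((3, 3), int) - np.eye(3, dtype=int))
        assert transitivity(g) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        a = np.zeros((4, 4), int)
        a[0, 1:] = 1
        a[1:, 0] = 1
        g = BinaryGraph(a)
        assert transitivity(g) == 0.0
        np.testing.assert_array_equal(nodal_clustering(g), np.zeros(4))

    def test_k3_member_clustering_one(self):
        g = BinaryGraph(np.ones((3, 3), int) - np.eye(3, dtype=int))
        np.testing.assert_allclose(nodal_clustering(g), 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("p_edge", [0.2, 0.5, 0.8])
    def test_metrics_match_brute_force(self, p_edge):
        rng = np.random.default_rng(int(p_edge * 100))
        for _ in range(35):
            n = int(rng.integers(4, 21))
            g = random_graph(rng, n, p_edge)
            adj = g.adjacency.astype(float)
            np.testing.assert_allclose(nodal_efficiency(g), brute_efficiency(adj))
            t = brute_triples(adj)
            k = adj.sum(axis=1)
            denom = (k * (k - 1)).sum()
            expected_t = 2 * t.sum() / denom if denom > 0 else 0.0
            assert transitivity(g) == pytest.approx(expected_t)
            expected_c = np.where(k >= 2, 2 * t / np.maximum(k * (k - 1), 1), 0.0)
            np.testing.assert_allclose(nodal_clustering(g), expected_c)
            np.testing.assert_array_equal(degree(g), k)

    def test_against_networkx(self, rng):
        for _ in range(20):
            g = random_graph(rng, int(rng.integers(5, 25)), 0.4)
            G = nx.from_numpy_array(g.adjacency)
            assert global_efficiency(g) == pytest.approx(
                nx.global_efficiency(G), abs=1e-12
            )
            assert transitivity(g) == pytest.approx(nx.transitivity(G), abs=1e-12)
            cl = nx.clustering(G)
            np.testing.assert_allclose(
                nodal_clustering(g), [cl[i] for i in range(g.n)], atol=1e-12
            )


class TestProportionalThreshold:
    def test_64_node_ten_percent_keeps_202_edges(self, rng):
        w = rng.random((64, 64))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        assert proportional_threshold(w, 0.10).n_edges == 202

    def test_full_threshold_gives_complete_graph(self, rng):
        w = rng.uniform(0.1, 1.0, (10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        g = proportional_threshold(w, 1.0)
        assert g.n_edges == 45

    def test_tie_break_deterministic(self):
        w = np.ones((8, 8)) * 0.5
        np.fill_diagonal(w, 0.0)
        g1 = proportional_threshold(w, 0.05)
        g2 = proportional_threshold(w, 0.05)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)

    def test_zero_edges_warns(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning):
            g = proportional_threshold(w, 0.01)
        assert g.n_edges == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nestedness_under_increasing_threshold(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        prev = None
        for p in (0.05, 0.15, 0.30, 0.60, 1.0):
            g = proportional_threshold(w, p)
            if prev is not None:
                assert ((prev.adjacency == 1) <= (g.adjacency == 1)).all()
            prev = g


class TestSweepAndAuc:
    def test_sweep_covers_36_thresholds(self, rng):
        w = rng.random((16, 16))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        curves = threshold_sweep(w)
        for curve in curves.values():
            assert len(curve.thresholds) == 36
        assert len(DEFAULT_THRESHOLDS) == 36

    def test_global_efficiency_nondecreasing_in_threshold(self, rng):
        for _ in range(5):
            w = rng.random((20, 20))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            curve = threshold_sweep(w, metrics=("global_efficiency",))[
                "global_efficiency"
            ]
            assert (np.diff(curve.values) >= -1e-12).all()

    def test_identical_inputs_identical_curves(self, rng):
        w = rng.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        c1 = threshold_sweep(w)["global_efficiency"]
        c2 = threshold_sweep(w.copy())["global_efficiency"]
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_constant_curve_auc(self):
        thr = np.asarray(DEFAULT_THRESHOLDS)
        curve = GraphMetricCurve(thr, np.full(36, 0.8), "global_efficiency", "global")
        assert metric_auc(curve).value == pytest.approx(0.35 * 0.8)

    def test_linear_ramp_auc(self):
        thr = np.asarray(DEFAULT_THRESHOLDS)
        ramp = (thr - thr[0]) / (thr[-1] - thr[0])
        curve = GraphMetricCurve(thr, ramp, "transitivity", "global")
        assert metric_auc(curve).value == pytest.approx(0.175)

    def test_two_point_trapezoid(self):
        curve = GraphMetricCurve(
            np.array([0.05, 0.40]), np.array([0.0, 1.0]), "x", "global"
        )
        assert metric_auc(curve).value == pytest.approx(0.175)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            metric_auc(
                GraphMetricCurve(np.array([0.05]), np.array([1.0]), "x", "global")
            )

    def test_bounded_metric_auc_in_range(self, rng):
        w = rng.random((16, 16))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        for name in ("global_efficiency", "transitivity"):
            auc = metric_auc(threshold_sweep(w, metrics=(name,))[name])
            assert 0.0 <= auc.value <= 0.35 + 1e-12
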