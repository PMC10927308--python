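"""Proportional thresholding and binary graph topology metrics.

Connectivity matrices are reduced to binary graphs by keeping a fixed top
fraction of the strongest weights (so all compared networks share edge
density), then characterized by integration (global/nodal efficiency) and
segregation (transitivity, nodal clustering).  Because any single density
is arbitrary, each metric is swept over thresholds 5%..40% in 1% steps and
summarized by the trapezoidal area under the curve (AUC).

Conventions for degenerate cases, fixed and deterministic: unreachable
node pairs contribute zero inverse distance; transitivity and clustering
are 0 when their denominators vanish; ties at the threshold cutoff break
by ascending (row, col) index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

#: Default proportional-threshold sweep: 5% to 40% in 1% increments.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    round(0.05 + 0.01 * i, 2) for i in range(36)
)

GLOBAL_METRICS = ("global_efficiency", "transitivity")
NODAL_METRICS = ("nodal_efficiency", "nodal_clustering", "degree")


@dataclass
class BinaryGraph:
    """Undirected unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8).copy()
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass
class GraphMetricCurve:
    """One graph statistic as a function of proportional threshold."""

    thresholds: np.ndarray
    values: np.ndarray  # (n_thresholds,) global or (n_thresholds, n) nodal
    metric_name: str
    level: str  # "global" | "nodal"

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.thresholds) != self.values.shape[0]:
            raise ValueError("thresholds/values length mismatch")
        if not (np.diff(self.thresholds) > 0).all():
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class AUCResult:
    value: float | np.ndarray
    metric_name: str
    level: str


def proportional_threshold(
    matrix: ConnectivityMatrix | np.ndarray, p: float
) -> BinaryGraph:
    """Keep the top fraction ``p`` of upper-triangle weights as edges.

    k = round(p * n(n-1)/2) edges are retained; ties at the cutoff break by
    ascending (row, col) order, making the edge set deterministic and
    nested across increasing ``p``.
    """
    w = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if not 0 < p <= 1:
        raise ValueError(f"threshold fraction must be in (0, 1], got {p}")
    n = w.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    weights = w[rows, cols]
    k = int(round(p * len(weights)))
    adj = np.zeros((n, n), dtype=np.int8)
    if k == 0:
        import warnings

        warnings.warn(f"threshold p={p} keeps zero edges", stacklevel=2)
        return BinaryGraph(adj)
    # sort by descending weight, ties by ascending (row, col)
    order = np.lexsort((cols, rows, -weights))
    keep = order[:k]
    adj[rows[keep], cols[keep]] = 1
    adj |= adj.T
    return BinaryGraph(adj)


def _inv_distances(graph: BinaryGraph) -> np.ndarray:
    """Matrix of 1/d_ij (0 for unreachable or i == j)."""
    d = shortest_path(csr_matrix(graph.adjacency), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def nodal_efficiency(graph: BinaryGraph) -> np.ndarray:
    """E_i = mean of 1/d_ij over the other n-1 nodes."""
    if graph.n < 2:
        return np.zeros(graph.n)
    return _inv_distances(graph).sum(axis=1) / (graph.n - 1)


def global_efficiency(graph: BinaryGraph) -> float:
    """E = mean nodal efficiency; 1 for a complete graph, 0 for edgeless."""
    if graph.n < 2:
        return 0.0
    return float(nodal_efficiency(graph).mean())


def _triangles_and_degree(graph: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    a = graph.adjacency.astype(np.float64)
    t = np.diag(a @ a @ a) / 2.0  # triangles through each node
    k = a.sum(axis=1)
    return t, k


def transitivity(graph: BinaryGraph) -> float:
    """Collectively normalized triangle density: sum 2t_i / sum k_i(k_i - 1)."""
    t, k = _triangles_and_degree(graph)
    denom = (k * (k - 1)).sum()
    return float(2.0 * t.sum() / denom) if denom > 0 else 0.0


def nodal_clustering(graph: BinaryGraph) -> np.ndarray:
    """C_i = 2t_i / (k_i (k_i - 1)); 0 for nodes of degree < 2."""
    t, k = _triangles_and_degree(graph)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def mean_clustering(graph: BinaryGraph) -> float:
    """Network-average clustering coefficient (mean of C_i)."""
    return float(nodal_clustering(graph).mean()) if graph.n else 0.0


def degree(graph: BinaryGraph) -> np.ndarray:
    """Unweighted node degree k_i."""
    return graph.adjacency.sum(axis=1).astype(float)


_METRIC_FUNCS = {
    "global_efficiency": (global_efficiency, "global"),
    "transitivity": (transitivity, "global"),
    "nodal_efficiency": (nodal_efficiency, "nodal"),
    "nodal_clustering": (nodal_clustering, "nodal"),
    "degree": (degree, "nodal"),
}


def threshold_sweep(
    matrix: ConnectivityMatrix | np.ndarray,
    metrics: tuple[str, ...] = GLOBAL_METRICS + ("nodal_efficiency", "nodal_clustering"),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> dict[str, GraphMetricCurve]:
    """Evaluate graph metrics on the binarized graph at every threshold."""
    unknown = set(metrics) - set(_METRIC_FUNCS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    graphs = [proportional_threshold(matrix, p) for p in thresholds]
    curves = {}
    for name in metrics:
        func, level = _METRIC_FUNCS[name]
        vals = np.array([func(g) for g in graphs])
        curves[name] = GraphMetricCurve(
            thresholds=np.asarray(thresholds), values=vals,
            metric_name=name, level=level,
        )
    return curves


def metric_auc(curve: GraphMetricCurve) -> AUCResult:
    """Trapezoidal integral of the metric over the threshold-fraction axis.

    For a constant value c over [0.05, 0.40] the AUC is 0.35 c; the AUC is
    not normalized by the range width (only differences are compared
    downstream).
    """
    if len(curve.thresholds) < 2:
        raise ValueError("AUC needs at least 2 threshold points")
    value = np.trapezoid(curve.values, curve.thresholds, axis=0)
    return AUCResult(
        value=float(value) if np.ndim(value) == 0 else value,
        metric_name=curve.metric_name,
        level=curve.level,
    )
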