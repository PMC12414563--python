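"""Weighted-directed graph metrics: global/local efficiency and degree
centralities, plus node-level group permutation tests.

Edge weights are connectivity strengths; higher weight means shorter
distance, so the length of an edge is the reciprocal of its weight (the
Brain Connectivity Toolbox convention for weighted shortest paths).  Global
efficiency (GE) is the average inverse directed shortest-path length over
all ordered node pairs (1/infinity = 0 for disconnected pairs); local
efficiency (LE) averages, over nodes, the GE of the subgraph induced by each
node's neighbors with the node itself removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .sparsify import permutation_ttest

__all__ = [
    "GlobalMetrics",
    "NodeCentrality",
    "NodeSignificance",
    "global_efficiency",
    "local_efficiency",
    "degree_centralities",
    "node_significance",
]


@dataclass
class GlobalMetrics:
    subject_id: str
    band: str
    GE: float
    LE: float


@dataclass
class NodeCentrality:
    subject_id: str
    band: str
    outdegree: np.ndarray  # row sums of A
    indegree: np.ndarray  # column sums of A


@dataclass
class NodeSignificance:
    band: str
    metric: str  # "outdegree" or "indegree"
    labels: list[str]
    p_raw: np.ndarray  # per-node permutation p
    p_bonferroni: np.ndarray
    significant_nodes: list[str]
    alpha: float
    t_obs: np.ndarray

    @property
    def significant_indices(self) -> list[int]:
        sig = set(self.significant_nodes)
        return [i for i, lab in enumerate(self.labels) if lab in sig]


def _validate_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("negative edge weight")
    if np.any(np.diag(A) != 0):
        raise ValueError("diagonal must be zero (no auto-loops)")
    return A


def _inverse_distance_sum(A: np.ndarray) -> float:
    """Sum over ordered pairs i != j of 1 / d_ij with edge length 1/weight."""
    n = A.shape[0]
    if n < 2 or not np.any(A):
        return 0.0
    rows, cols = np.nonzero(A)
    lengths = 1.0 / A[rows, cols]
    graph = csr_matrix((lengths, (rows, cols)), shape=(n, n))
    d = shortest_path(graph, method="D", directed=True)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum())


def global_efficiency(A: np.ndarray) -> float:
    """GE = (1/(n(n-1))) * sum_{i != j} 1/d_ij, d from lengths 1/A_ij."""
    A = _validate_adjacency(A)
    n = A.shape[0]
    if n < 2:
        return 0.0
    return _inverse_distance_sum(A) / (n * (n - 1))


def local_efficiency(A: np.ndarray) -> float:
    """Mean over nodes of the GE of each node's neighbor subgraph.

    Neighbors of node i are nodes with an in- or out-edge with i; the
    subgraph excludes i itself.  Nodes with fewer than 2 neighbors
    contribute 0.
    """
    A = _validate_adjacency(A)
    n = A.shape[0]
    if n == 0:
        return 0.0
    connected = (A > 0) | (A.T > 0)
    acc = 0.0
    for i in range(n):
        nbrs = np.nonzero(connected[i])[0]
        nbrs = nbrs[nbrs != i]
        if nbrs.size < 2:
            continue
        acc += global_efficiency(A[np.ix_(nbrs, nbrs)])
    return acc / n


def degree_centralities(A: np.ndarray, *, subject_id: str = "",
                        band: str = "") -> NodeCentrality:
    """Outdegree_i = sum_j A_ij (row sum); Indegree_i = sum_j A_ji (column
    sum)."""
    A = _validate_adjacency(A)
    return NodeCentrality(subject_id=subject_id, band=band,
                          outdegree=A.sum(axis=1), indegree=A.sum(axis=0))


def node_significance(
    low: list[NodeCentrality] | np.ndarray,
    high: list[NodeCentrality] | np.ndarray,
    metric: str,
    n_perm: int = 5000,
    seed: int = 0,
    *,
    labels: list[str] | None = None,
    band: str = "",
    alpha: float = 0.05,
) -> NodeSignificance:
    """Per-node two-tailed permutation t-test with Bonferroni correction.

    The Bonferroni factor is the number of nodes (per band, per metric);
    a node is significant when p_raw * n_nodes < alpha.
    """
    if metric not in ("outdegree", "indegree"):
        raise ValueError("metric must be 'outdegree' or 'indegree'")

    def stack(group):
        if len(group) and isinstance(group[0], NodeCentrality):
            arr = np.asarray([getattr(c, metric) for c in group])
        else:
            arr = np.asarray(group)
        return np.atleast_2d(arr.astype(float))

    low_v, high_v = stack(low), stack(high)
    if low_v.shape[1] != high_v.shape[1]:
        raise ValueError("groups have different node counts")
    n_nodes = low_v.shape[1]
    if labels is None:
        labels = [f"R{i + 1:02d}" for i in range(n_nodes)]
    if len(labels) != n_nodes:
        raise ValueError("labels length mismatch")
    t_obs, p_raw = permutation_ttest(low_v, high_v, n_perm, seed)
    p_bonf = np.minimum(1.0, p_raw * n_nodes)
    sig = [labels[i] for i in range(n_nodes) if p_raw[i] * n_nodes < alpha]
    return NodeSignificance(band=band, metric=metric, labels=list(labels),
                            p_raw=p_raw, p_bonferroni=p_bonf,
                            significant_nodes=sig, alpha=alpha, t_obs=t_obs)
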