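"""Functional connectivity networks and their graph-theoretic properties.

Node time series (e.g. regional BOLD signals on a 90-region atlas) are
correlated pairwise, Fisher-z transformed into a :class:`ConnectivityNetwork`,
thresholded to a binary graph at a chosen edge density (sparsity), and
summarized by the clustering coefficient, nodal efficiency (NE), nodal
local efficiency (NLE) and their global averages (aCp, aEloc).

The thresholding scheme is explicit configuration, never a silent default
in reports: binary graphs at a stated sparsity, edges ranked by |z| (sign
handling configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ArgumentError, DegenerateNodeError

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityNetwork:
    """Symmetric Fisher-z correlation matrix with zero diagonal and node labels."""

    z_matrix: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        n = z.shape[0]
        if z.ndim != 2 or z.shape[1] != n:
            raise ArgumentError("z_matrix must be square")
        if len(self.node_labels) != n:
            raise ArgumentError("node_labels length must match matrix size")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ArgumentError("z_matrix must be symmetric")
        if not np.allclose(np.diag(z), 0.0):
            raise ArgumentError("z_matrix diagonal must be zero")
        object.__setattr__(self, "z_matrix", z)

    @property
    def n_nodes(self) -> int:
        return self.z_matrix.shape[0]


def build_fcn(time_series: np.ndarray, node_labels=None) -> ConnectivityNetwork:
    """Pairwise Pearson correlation of node time series, Fisher-z transformed.

    ``time_series`` is nodes x time.  |r| is clipped just below 1 before
    atanh so duplicated nodes yield a large finite z rather than infinity;
    the diagonal is zeroed.  A constant node series raises
    :class:`DegenerateNodeError` naming the node.
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ArgumentError("time_series must be nodes x time with T >= 3")
    sds = ts.std(axis=1)
    dead = np.nonzero(sds == 0)[0]
    if dead.size:
        raise DegenerateNodeError(f"constant time series at node index {dead[0]}")
    r = np.corrcoef(ts)
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    if node_labels is None:
        node_labels = tuple(f"node{i}" for i in range(ts.shape[0]))
    return ConnectivityNetwork(z_matrix=z, node_labels=tuple(node_labels))


def threshold_network(
    net: ConnectivityNetwork, sparsity: float, use_magnitude: bool = True
) -> np.ndarray:
    """Binary adjacency keeping the top ``sparsity`` fraction of edges.

    Edges are ranked by |z| (or signed z when ``use_magnitude`` is False)
    with a deterministic tie-break by (value, node-index pair); the result
    is symmetric with no self-loops.
    """
    if not 0.0 < sparsity < 1.0:
        raise ArgumentError(f"sparsity must lie in (0, 1), got {sparsity}")
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    weights = net.z_matrix[iu, ju]
    key = np.abs(weights) if use_magnitude else weights
    n_keep = int(round(sparsity * key.size))
    n_keep = max(1, min(key.size, n_keep))
    # stable sort descending by value, then ascending (i, j) for ties
    order = np.lexsort((ju, iu, -key))
    keep = order[:n_keep]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return adj


def _check_adj(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ArgumentError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ArgumentError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ArgumentError("adjacency must have a zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ArgumentError("adjacency must be binary")
    return adj


def _graph(adj: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(adj))


def nodal_metrics(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nodal efficiency and nodal local efficiency of a binary graph.

    NE(i) = mean over j != i of 1/d(i, j) with unweighted shortest-path
    distances and 1/inf = 0; NLE(i) is the global efficiency of the subgraph
    induced by i's neighbors (0 for degree < 2).
    """
    adj = _check_adj(adj)
    n = adj.shape[0]
    G = _graph(adj)
    ne = np.zeros(n)
    nle = np.zeros(n)
    if n < 2:
        return ne, nle
    for i in range(n):
        lengths = nx.single_source_shortest_path_length(G, i)
        ne[i] = sum(1.0 / d for node, d in lengths.items() if node != i) / (n - 1)
        neighbors = list(G.neighbors(i))
        if len(neighbors) >= 2:
            nle[i] = nx.global_efficiency(G.subgraph(neighbors))
    return ne, nle


def global_metrics(adj: np.ndarray) -> tuple[float, float]:
    """Average clustering coefficient (aCp) and average local efficiency (aEloc).

    Nodal clustering is 2*triangles / (deg*(deg-1)), zero for degree < 2;
    aCp averages it over nodes, and aEloc averages the nodal local
    efficiency.  An empty graph yields zeros.
    """
    adj = _check_adj(adj)
    if adj.shape[0] == 0:
        return 0.0, 0.0
    G = _graph(adj)
    acp = float(np.mean(list(nx.clustering(G).values())))
    _, nle = nodal_metrics(adj)
    return acp, float(np.mean(nle))


def metrics_report(
    net: ConnectivityNetwork, sparsity: float = 0.2, use_magnitude: bool = True
) -> dict:
    """Threshold a network and compute all graph metrics, echoing the configuration."""
    adj = threshold_network(net, sparsity, use_magnitude=use_magnitude)
    ne, nle = nodal_metrics(adj)
    acp, aeloc = global_metrics(adj)
    return {
        "sparsity": sparsity,
        "edge_ranking": "|z|" if use_magnitude else "z",
        "aCp": acp,
        "aEloc": aeloc,
        "NE": ne,
        "NLE": nle,
        "node_labels": list(net.node_labels),
    }


def sparsity_sweep(
    net: ConnectivityNetwork, sparsities, use_magnitude: bool = True
) -> "list[dict]":
    """Metric-vs-sparsity curves over a sweep of edge densities."""
    return [metrics_report(net, s, use_magnitude=use_magnitude) for s in sparsities]
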