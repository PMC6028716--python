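"""Weighted graph metrics for connectivity-probability networks.

Implements, from first principles, the properties used to characterize
weighted structural connectomes:

* **global efficiency** — mean inverse shortest-path length over all
  unordered node pairs (1/inf := 0 for disconnected pairs);
* **nodal local efficiency** — global efficiency of the subnetwork
  induced on a node's direct neighbors (original weights retained;
  0 for degree < 2); its node-mean is the network's local efficiency;
* **weighted clustering coefficient** — Onnela's geometric-mean triangle
  form with weights normalized by the network maximum;
* **betweenness centrality** — Brandes' algorithm over weighted shortest
  paths, unnormalized, summed over unordered source-target pairs;
* **nodal degree** and **mean connectivity strength** (mean weight over
  nonzero edges).

Edge weights are connection probabilities, so the weight-to-distance
mapping is the reciprocal d = 1/w: stronger connections are shorter.
All-pairs distances use a vectorized Floyd-Warshall; Brandes uses a
binary-heap Dijkstra per source.  Disconnected pairs contribute zero
efficiency and zero betweenness rather than raising, so the attack
simulation can fragment networks gracefully.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .atlas_io import WeightedNetwork

__all__ = [
    "MetricSet", "edge_distances", "shortest_path_lengths",
    "global_efficiency", "nodal_degree", "mean_connectivity_strength",
    "clustering_coefficient", "nodal_local_efficiency",
    "betweenness_centrality", "compute_metric_set",
    "GLOBAL_METRICS", "NODAL_PROPERTIES",
]

GLOBAL_METRICS = (
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "mean_connectivity_strength",
)
NODAL_PROPERTIES = ("local_efficiency", "degree", "betweenness_centrality")


@dataclass
class MetricSet:
    """All global scalars and nodal vectors for one subject's network."""

    subject_id: str
    global_efficiency: float
    local_efficiency_mean: float
    clustering_coefficient_mean: float
    betweenness_mean: float
    mean_connectivity_strength: float
    nodal_local_efficiency: np.ndarray
    nodal_degree: np.ndarray
    nodal_betweenness: np.ndarray

    def globals_dict(self) -> dict[str, float]:
        return {
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency_mean,
            "clustering_coefficient": self.clustering_coefficient_mean,
            "betweenness_centrality": self.betweenness_mean,
            "mean_connectivity_strength": self.mean_connectivity_strength,
        }


def _weights(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        return net.weights
    return np.asarray(net, dtype=float)


def edge_distances(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Reciprocal weight-to-distance map: d = 1/w, inf for absent edges."""
    W = _weights(net)
    with np.errstate(divide="ignore"):
        D = np.where(W > 0.0, 1.0 / np.where(W > 0.0, W, 1.0), np.inf)
    np.fill_diagonal(D, 0.0)
    return D


def _floyd_warshall_numpy(D: np.ndarray) -> np.ndarray:
    D = D.copy()
    n = D.shape[0]
    for k in range(n):
        np.minimum(D, D[:, k, None] + D[None, k, :], out=D)
    return D


try:  # optional JIT of the same relaxation loop; results are identical
    from numba import njit

    @njit(cache=False)
    def _fw_kernel(D: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        for k in range(n):
            for i in range(n):
                dik = D[i, k]
                for j in range(n):
                    alt = dik + D[k, j]
                    if alt < D[i, j]:
                        D[i, j] = alt
        return D

    def _floyd_warshall(D: np.ndarray) -> np.ndarray:
        return _fw_kernel(D.copy())

except ImportError:  # pragma: no cover
    _floyd_warshall = _floyd_warshall_numpy


def shortest_path_lengths(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest distances over the reciprocal edge distances."""
    return _floyd_warshall(edge_distances(net))


def _efficiency_from_distances(SP: np.ndarray) -> float:
    n = SP.shape[0]
    iu = np.triu_indices(n, k=1)
    d = SP[iu]
    inv = np.where(np.isfinite(d) & (d > 0.0), 1.0 / np.where(d > 0.0, d, 1.0), 0.0)
    return float(inv.sum() / len(d))


def global_efficiency(net: WeightedNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over all unordered pairs."""
    W = _weights(net)
    if W.shape[0] < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    return _efficiency_from_distances(shortest_path_lengths(W))


def nodal_degree(net: WeightedNetwork | np.ndarray) -> np.ndarray:
    """Number of connections per node (count of nonzero weights)."""
    return (_weights(net) > 0.0).sum(axis=1).astype(np.int64)


def mean_connectivity_strength(net: WeightedNetwork | np.ndarray) -> float:
    """Mean weight over nonzero undirected edges."""
    W = _weights(net)
    iu = np.triu_indices(W.shape[0], k=1)
    w = W[iu]
    nz = w[w > 0.0]
    if nz.size == 0:
        raise ValueError("mean connectivity strength undefined on edgeless network")
    return float(nz.mean())


def clustering_coefficient(
    net: WeightedNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering (max-weight normalized).

    With w_hat = W / max(W), C_i is the mean over ordered neighbor pairs
    (j, h) of the geometric mean of the triangle weights,
    (w_hat_ij * w_hat_ih * w_hat_jh)^(1/3), i.e. the cube-root-matrix
    triangle count divided by k_i (k_i - 1); C_i = 0 for degree < 2.
    Returns (nodal vector, mean over all nodes).
    """
    W = _weights(net)
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0.0:
        return np.zeros(n), 0.0
    w13 = np.cbrt(W / wmax)
    tri = np.einsum("ij,jh,hi->i", w13, w13, w13)
    k = nodal_degree(W).astype(float)
    denom = k * (k - 1.0)
    C = np.where(denom > 0.0, tri / np.where(denom > 0.0, denom, 1.0), 0.0)
    return C, float(C.mean())


def nodal_local_efficiency(
    net: WeightedNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-node efficiency of the neighbor-induced subnetwork.

    E_loc(i) is the global efficiency of the subgraph induced on the
    direct neighbors of i with the original edge weights; paths through
    non-neighbors (including i itself) do not count.  Zero for nodes
    with fewer than two neighbors.  Returns (nodal vector, mean).
    """
    W = _weights(net)
    n = W.shape[0]
    E = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0.0)
        if nbrs.size < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        E[i] = _efficiency_from_distances(shortest_path_lengths(sub))
    return E, float(E.mean())


def betweenness_centrality(
    net: WeightedNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Brandes betweenness on the reciprocal-weight distances.

    BC_i sums, over unordered pairs (s, t) with s != i != t, the
    fraction of shortest s-t paths passing through i.  Unnormalized;
    disconnected pairs contribute nothing.  Returns (nodal vector, mean).
    """
    W = _weights(net)
    n = W.shape[0]
    BC = np.zeros(n)
    adj: list[list[tuple[int, float]]] = [
        [(j, 1.0 / W[i, j]) for j in np.flatnonzero(W[i] > 0.0)]
        for i in range(n)
    ]
    for s in range(n):
        # single-source Dijkstra with shortest-path counts
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u, duv in adj[v]:
                nd = d + duv
                if nd < dist[u]:
                    dist[u] = nd
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (nd, u))
                elif nd == dist[u] and not done[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        # dependency accumulation in reverse finish order
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                BC[v] += delta[v]
    BC /= 2.0  # each unordered pair visited from both endpoints
    return BC, float(BC.mean())


def compute_metric_set(net: WeightedNetwork) -> MetricSet:
    """Assemble every global scalar and nodal vector for one network."""
    eff = global_efficiency(net)
    eloc, eloc_mean = nodal_local_efficiency(net)
    _, clust_mean = clustering_coefficient(net)
    bc, bc_mean = betweenness_centrality(net)
    return MetricSet(
        subject_id=net.subject_id,
        global_efficiency=eff,
        local_efficiency_mean=eloc_mean,
        clustering_coefficient_mean=clust_mean,
        betweenness_mean=bc_mean,
        mean_connectivity_strength=mean_connectivity_strength(net),
        nodal_local_efficiency=eloc,
        nodal_degree=nodal_degree(net),
        nodal_betweenness=bc,
    )
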