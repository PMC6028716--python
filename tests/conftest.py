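"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms:
shortest paths, path counts and betweenness come from exhaustive
simple-path enumeration (feasible for n <= 8), clustering and local
efficiency from direct evaluation of their defining formulas.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from strucnet.atlas_io import AtlasNodeTable, WeightedNetwork, make_atlas

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas87():
    from strucnet.atlas_io import default_atlas
    return default_atlas()


def build_network(n: int, edges: list[tuple[int, int, float]],
                  subject_id: str = "s") -> WeightedNetwork:
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return WeightedNetwork(W, make_atlas(n), subject_id)


@pytest.fixture
def triangle():
    return build_network(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 0.5)])


@pytest.fixture
def path3():
    return build_network(3, [(0, 1, 1.0), (1, 2, 1.0)])


def complete_network(n: int, w: float = 1.0) -> WeightedNetwork:
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(W, make_atlas(n))


def random_network(rng: np.random.Generator, n: int,
                   p_edge: float = 0.5) -> WeightedNetwork:
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
    return WeightedNetwork(W, make_atlas(n))


# ---------------------------------------------------------------- oracles

def brute_shortest_paths(W: np.ndarray, tol: float = 1e-12):
    """Exhaustive simple-path enumeration over d = 1/w.

    Returns (dist, sigma, through) where sigma[s, t] counts shortest
    s-t paths and through[s][t] maps intermediate node -> number of
    shortest paths crossing it.
    """
    n = W.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.zeros((n, n))
    through: list[list[dict]] = [[{} for _ in range(n)] for _ in range(n)]
    adj = [np.flatnonzero(W[i] > 0.0) for i in range(n)]
    for s in range(n):
        for t in range(n):
            if t <= s:
                continue
            best, paths = np.inf, []
            stack = [(s, (s,), 0.0)]
            while stack:
                v, path, length = stack.pop()
                if length > best + tol:
                    continue
                if v == t:
                    if length < best - tol:
                        best, paths = length, [path]
                    elif abs(length - best) <= tol:
                        paths.append(path)
                    continue
                for u in adj[v]:
                    if u not in path:
                        stack.append((u, path + (int(u),), length + 1.0 / W[v, u]))
            if not paths:
                continue
            dist[s, t] = dist[t, s] = best
            sigma[s, t] = sigma[t, s] = len(paths)
            inter: dict[int, int] = {}
            for p in paths:
                for v in p[1:-1]:
                    inter[v] = inter.get(v, 0) + 1
            through[s][t] = inter
    return dist, sigma, through


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    dist, sigma, through = brute_shortest_paths(W)
    n = W.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if sigma[s, t] == 0:
                continue
            for v, cnt in through[s][t].items():
                bc[v] += cnt / sigma[s, t]
    return bc


def brute_global_efficiency(W: np.ndarray) -> float:
    dist, _, _ = brute_shortest_paths(W)
    n = W.shape[0]
    acc = 0.0
    for s in range(n):
        for t in range(s + 1, n):
            if math.isfinite(dist[s, t]) and dist[s, t] > 0:
                acc += 1.0 / dist[s, t]
    return acc / (n * (n - 1) / 2)


def brute_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    wh = W / wmax
    C = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for j, h in itertools.permutations(nbrs, 2):
            acc += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        C[i] = acc / (k * (k - 1))
    return C


def brute_local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    E = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        if len(nbrs) < 2:
            continue
        E[i] = brute_global_efficiency(W[np.ix_(nbrs, nbrs)])
    return E


def nx_graph(net: WeightedNetwork):
    """networkx view with both weight and reciprocal distance attributes."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(net.n_nodes))
    for i, j, w in net.edge_list():
        G.add_edge(i, j, weight=w, distance=1.0 / w)
    return G
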