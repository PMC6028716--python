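"""From streamline counts to the thresholded weighted network.

Reconstruction has three steps: per-seed counts are converted to
connection probabilities (count divided by the seed's way-total), the
directed probabilities are symmetrized by averaging the two tracking
directions, and the weakest fraction of the surviving undirected edges
(default: the lowest 10% of each subject's nonzero connections) is
discarded to suppress spurious connections.

"Lowest 10% of connections" is interpreted as 10% of *nonzero*
undirected edges of that subject's network — zero entries are
non-connections and per-subject normalization keeps the rule comparable
across subjects.  The number removed is floor(fraction * m); ties on
weight are broken by ascending (weight, smaller node id, larger node
id), so the result is deterministic.  No binarization is applied
anywhere: all downstream metrics stay weighted.
"""

from __future__ import annotations

import numpy as np

from .atlas_io import AtlasNodeTable, WeightedNetwork
from .synthetic_data import TractographyRun

__all__ = [
    "connection_probability", "symmetrize", "threshold_network", "reconstruct",
]


def connection_probability(run: TractographyRun) -> np.ndarray:
    """Directed connection probabilities P[i, j] = counts[i, j] / waytotal[i]."""
    if np.any(run.waytotals <= 0):
        bad = int(np.flatnonzero(run.waytotals <= 0)[0])
        raise ValueError(f"seed node {bad} has zero way-total")
    P = run.counts / run.waytotals[:, None]
    np.fill_diagonal(P, 0.0)
    return P


def symmetrize(
    P: np.ndarray, atlas: AtlasNodeTable, subject_id: str = ""
) -> WeightedNetwork:
    """Average the two tracking directions: W[i, j] = (P[i, j] + P[j, i]) / 2."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"probability matrix must be square, got {P.shape}")
    W = (P + P.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(W, atlas, subject_id)


def threshold_network(
    net: WeightedNetwork, fraction: float = 0.10
) -> WeightedNetwork:
    """Discard the weakest ``fraction`` of the nonzero undirected edges.

    With m nonzero edges, the floor(fraction * m) smallest-weight edges
    are zeroed (ties by ascending weight, then smaller node id, then
    larger node id); every surviving weight is unchanged.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    edges = net.edge_list()
    k = int(np.floor(fraction * len(edges)))
    W = net.weights.copy()
    if k > 0:
        edges.sort(key=lambda e: (e[2], e[0], e[1]))
        for i, j, _ in edges[:k]:
            W[i, j] = 0.0
            W[j, i] = 0.0
    return WeightedNetwork(W, net.atlas, net.subject_id)


def reconstruct(
    run: TractographyRun, atlas: AtlasNodeTable, fraction: float = 0.10
) -> WeightedNetwork:
    """Full reconstruction: probabilities -> symmetrize -> threshold."""
    return threshold_network(
        symmetrize(connection_probability(run), atlas, run.subject_id), fraction
    )
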