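"""Node centrality indices on the weighted partial-correlation network.

Strength is the sum of absolute incident edge weights.  Closeness and
betweenness are shortest-path indices under the standard weighted-graph
convention of edge length ``1 / |w_ij|``: closeness is the inverse of the
total distance to all other nodes (0 when any peer is unreachable), and
betweenness counts, with fractional credit for ties, how many shortest paths
between other node pairs pass through each node.  All three depend only on
the absolute weights.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .network import EDGE_ZERO_THRESHOLD

__all__ = ["strength", "node_distances", "closeness", "betweenness", "centrality_profile"]


def _as_weights(weights) -> np.ndarray:
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    W = np.abs(0.5 * (W + W.T))
    np.fill_diagonal(W, 0.0)
    W[W <= EDGE_ZERO_THRESHOLD] = 0.0
    return W


def strength(weights) -> np.ndarray:
    """Per-node sum of absolute incident edge weights."""
    return _as_weights(weights).sum(axis=1)


def node_distances(weights) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/|w| (Dijkstra).

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    W = _as_weights(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)  # 0 encodes "no edge" for csgraph
    return dijkstra(lengths, directed=False)


def closeness(weights) -> np.ndarray:
    """Inverse total shortest-path distance; 0 for nodes with unreachable peers."""
    d = node_distances(weights)
    p = d.shape[0]
    out = np.zeros(p)
    for i in range(p):
        others = np.delete(d[i], i)
        if np.all(np.isfinite(others)) and others.sum() > 0:
            out[i] = 1.0 / others.sum()
    return out


def betweenness(weights) -> np.ndarray:
    """Shortest-path betweenness (Brandes), unnormalized, ties split equally."""
    W = _as_weights(weights)
    p = W.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] > 0:
                g.add_edge(i, j, length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(p)])


def centrality_profile(weights, node_labels=None, *, standardize: bool = False) -> pd.DataFrame:
    """Strength, closeness, and betweenness per node as a table.

    Raw coefficients by default; ``standardize=True`` z-scores each index
    across nodes.
    """
    W = _as_weights(weights)
    labels = list(node_labels) if node_labels is not None else list(range(W.shape[0]))
    out = pd.DataFrame(
        {
            "strength": strength(W),
            "closeness": closeness(W),
            "betweenness": betweenness(W),
        },
        index=pd.Index(labels, name="node"),
    )
    if standardize:
        out = (out - out.mean()) / out.std(ddof=1)
    return out
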