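"""Graph measures on wPLI adjacency matrices.

Node strength is the summed connection weight of each region. Global
efficiency (GE) is the mean inverse shortest-path length over region
pairs on the weighted graph whose edge *lengths* are inverse connection
weights (strong connections are short); disconnected pairs contribute
zero efficiency. Metrics are computed on the full weighted matrices —
no thresholding or binarisation.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .containers import AdjacencyMatrix


def _as_square(adj) -> np.ndarray:
    values = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("adjacency must be square")
    return values


def node_strength(adj) -> np.ndarray:
    """Per-parcel strength: row sums of the adjacency excluding the diagonal."""
    values = _as_square(adj)
    if not np.allclose(values, values.T):
        raise ValueError("adjacency must be symmetric")
    return values.sum(axis=1) - np.diag(values)


def inverse_length(adj) -> np.ndarray:
    """Edge lengths as reciprocal weights: 1/w, with 0 -> inf and diagonal 0."""
    values = _as_square(adj)
    if np.any(values < 0):
        raise ValueError("weights must be non-negative")
    with np.errstate(divide="ignore"):
        lengths = np.where(values > 0, 1.0 / np.maximum(values, 1e-300), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_lengths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path closure of a non-negative length matrix.

    Infinite entries mean "no direct edge"; the result may still be finite
    there via multi-hop paths. Computed with Dijkstra per source.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("lengths must be non-negative")
    finite = np.isfinite(lengths) & (lengths > 0)
    graph = csr_matrix((lengths[finite], np.nonzero(finite)), shape=lengths.shape)
    d = dijkstra(graph, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(d: np.ndarray) -> float:
    """Mean over off-diagonal pairs of 1/d(i,j), with 1/inf := 0.

    ``d`` must already be a shortest-path closure.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.maximum(d, 1e-300), 0.0)
    return float(inv[off].mean())


def graph_metrics(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Convenience: (node strength, global efficiency) for one adjacency."""
    strength = node_strength(adj)
    ge = global_efficiency(shortest_path_lengths(inverse_length(adj)))
    return strength, ge
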