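"""Weighted graph metrics for connectomes.

All metrics operate on a symmetric non-negative weight matrix with zero
diagonal (weights in [0, 1], absolute partial correlations).  The
connection-length convention is ``length = 1 / weight``: stronger edges are
shorter.  Shortest paths use Dijkstra (scipy); betweenness uses Brandes
accumulation (igraph); clustering is the Onnela geometric-mean form; local
efficiency is the cube-root weighted neighbourhood-efficiency variant; and
assortativity is the edge-weighted Pearson correlation of excess endpoint
strengths, with an exactly conservative per-node decomposition.

Undefined values (path length of a disconnected node, assortativity of a
perfectly regular graph) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import igraph as ig
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.sparse.csgraph import floyd_warshall as _floyd_warshall

from .connectome import Connectome

__all__ = [
    "weight_to_length",
    "all_pairs_shortest_paths",
    "nodal_shortest_path_length",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_onnela",
    "local_efficiency",
    "nodal_strength",
    "betweenness_centrality",
    "global_assortativity",
    "local_assortativity",
    "compute_all_metrics",
    "NODAL_METRICS",
    "WHOLEBRAIN_METRICS",
]

NODAL_METRICS = [
    "strength",
    "clustering",
    "local_efficiency",
    "betweenness",
    "path_length",
    "assortativity",
]

WHOLEBRAIN_METRICS = [
    "global_efficiency",
    "mean_local_efficiency",
    "characteristic_path_length",
    "global_clustering",
    "global_assortativity",
]


def _as_weights(w) -> np.ndarray:
    if isinstance(w, Connectome):
        return w.weights
    w = np.asarray(w, dtype=float)
    return w


def weight_to_length(weights) -> np.ndarray:
    """Map weights to connection lengths: 1/w for w > 0, +inf otherwise."""
    w = _as_weights(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _length_graph(lengths: np.ndarray) -> csr_matrix:
    """Sparse graph from a length matrix (inf = absent edge)."""
    l = lengths.copy()
    l[~np.isfinite(l)] = 0.0  # csr: explicit zeros dropped = absent
    np.fill_diagonal(l, 0.0)
    return csr_matrix(l)


def all_pairs_shortest_paths(lengths: np.ndarray, return_predecessors: bool = False):
    """All-pairs shortest-path distances via Dijkstra.

    ``lengths`` uses +inf for absent edges and must be non-negative.
    Returns the distance matrix, optionally with the predecessor matrix.
    """
    l = np.asarray(lengths, dtype=float)
    finite = l[np.isfinite(l)]
    if finite.size and finite.min() < 0:
        raise ValueError("connection lengths must be non-negative")
    res = _dijkstra(
        _length_graph(l), directed=False, return_predecessors=return_predecessors
    )
    return res


def nodal_shortest_path_length(distances: np.ndarray) -> np.ndarray:
    """Mean finite distance from each node to the others (NaN if isolated)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        row = np.delete(d[i], i)
        finite = row[np.isfinite(row)]
        if finite.size:
            out[i] = finite.mean()
    return out


def characteristic_path_length(distances: np.ndarray) -> tuple[float, float]:
    """Mean finite distance over unordered pairs.

    Returns ``(value, excluded_fraction)`` where the second element is the
    fraction of pairs excluded because they are disconnected.
    """
    d = np.asarray(distances, dtype=float)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite node pair: characteristic path length undefined")
    return float(vals[finite].mean()), float(1.0 - finite.mean())


def global_efficiency(distances: np.ndarray) -> float:
    """Mean inverse distance over unordered pairs (1/inf = 0)."""
    d = np.asarray(distances, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(vals > 0, 1.0 / np.where(vals > 0, vals, 1.0), 0.0)
    inv[~np.isfinite(vals)] = 0.0
    return float(inv.mean())


def nodal_strength(weights) -> np.ndarray:
    """Sum of incident weights per node."""
    return _as_weights(weights).sum(axis=1)


def clustering_onnela(weights) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    c_i = 2/(k_i (k_i - 1)) * sum_{j<h} (w'_ij w'_jh w'_ih)^(1/3), with
    weights normalized by the network-wide maximum; c_i = 0 for degree < 2.
    """
    w = _as_weights(weights)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    w13 = np.cbrt(w / wmax)
    cyc = np.diag(w13 @ w13 @ w13)  # 2 * sum over j<h of triangle intensities
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cyc / denom, 0.0)
    return c


def local_efficiency(weights) -> np.ndarray:
    """Weighted local efficiency per node (cube-root variant).

    e_i = 1/(k_i (k_i - 1)) * sum over ordered neighbour pairs (j, h) of
    (w'_ij w'_ih)^(1/3) / d_jh, where d_jh is the shortest path between j
    and h *within the subgraph induced by i's neighbours*, computed on
    cube-rooted connection lengths (1/w')^(1/3); unreachable neighbour
    pairs contribute 0, and e_i = 0 for degree < 2.
    """
    w = _as_weights(weights)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    wn13 = np.cbrt(wn)
    with np.errstate(divide="ignore"):
        len13 = np.where(wn > 0, 1.0 / np.where(wn > 0, wn13, 1.0), np.inf)
    np.fill_diagonal(len13, 0.0)

    out = np.zeros(n)
    for i in range(n):
        nbr = np.flatnonzero(wn[i] > 0)
        k = nbr.size
        if k < 2:
            continue
        d = _floyd_warshall(len13[np.ix_(nbr, nbr)], directed=False)
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
        dinv[~np.isfinite(d)] = 0.0
        np.fill_diagonal(dinv, 0.0)
        wi13 = wn13[i, nbr]
        out[i] = float(wi13 @ dinv @ wi13) / (k * (k - 1))
    return out


def betweenness_centrality(lengths) -> np.ndarray:
    """Weighted betweenness per node: sum over unordered pairs (s, t) of the
    fraction of shortest s-t paths passing through the node (Brandes
    accumulation, unnormalized counts)."""
    l = np.asarray(lengths, dtype=float)
    finite = l[np.isfinite(l)]
    if finite.size and finite.min() < 0:
        raise ValueError("connection lengths must be non-negative")
    n = l.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = np.isfinite(l[iu]) & (l[iu] > 0)
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    if not edges:
        return np.zeros(n)
    return np.asarray(g.betweenness(weights=l[iu][mask].tolist()), dtype=float)


def _edge_endpoint_table(w: np.ndarray):
    """Directed edge list with excess endpoint strengths.

    For every ordered edge (i, j) with weight w_ij > 0: x = s_i - w_ij,
    y = s_j - w_ij (the strength of each endpoint excluding the edge
    itself).  Both orientations are included so the correlation is
    symmetric in the two endpoints.
    """
    s = w.sum(axis=1)
    src, dst = np.nonzero(w)
    wts = w[src, dst]
    x = s[src] - wts
    y = s[dst] - wts
    return src, dst, wts, x, y


def global_assortativity(weights) -> float:
    """Edge-weighted Pearson correlation of excess endpoint strengths.

    Returns NaN when fewer than 2 edges exist or the endpoint strengths
    have zero variance (e.g. a perfectly regular graph).
    """
    w = _as_weights(weights)
    src, dst, wts, x, y = _edge_endpoint_table(w)
    if len(wts) < 4:  # fewer than 2 undirected edges
        return float("nan")
    wsum = wts.sum()
    xm = (wts * x).sum() / wsum
    ym = (wts * y).sum() / wsum
    sxx = (wts * (x - xm) ** 2).sum()
    syy = (wts * (y - ym) ** 2).sum()
    if sxx <= 0 or syy <= 0:
        return float("nan")
    sxy = (wts * (x - xm) * (y - ym)).sum()
    return float(sxy / np.sqrt(sxx * syy))


def local_assortativity(weights) -> np.ndarray:
    """Per-node decomposition of global assortativity.

    Each directed edge's contribution to the weighted endpoint-strength
    correlation is assigned to its source node, so the nodal values sum to
    the global coefficient exactly; a node with no edges contributes 0.
    All values are NaN when the global coefficient is undefined.
    """
    w = _as_weights(weights)
    n = w.shape[0]
    r = global_assortativity(w)
    if np.isnan(r):
        return np.full(n, np.nan)
    src, dst, wts, x, y = _edge_endpoint_table(w)
    wsum = wts.sum()
    xm = (wts * x).sum() / wsum
    ym = (wts * y).sum() / wsum
    sxx = (wts * (x - xm) ** 2).sum()
    syy = (wts * (y - ym) ** 2).sum()
    contrib = wts * (x - xm) * (y - ym) / np.sqrt(sxx * syy)
    out = np.zeros(n)
    np.add.at(out, src, contrib)
    return out


def compute_all_metrics(conn) -> tuple[pd.DataFrame, dict]:
    """All nodal and whole-brain metrics with consistent floating-node
    handling.

    Floating nodes (no connections) get NaN path length, zero strength /
    clustering / betweenness, and are excluded from every whole-brain
    aggregate, so the whole-brain values equal those of the graph with the
    floating nodes removed.

    Returns a nodal DataFrame (region x metric) and a whole-brain dict.
    """
    w = _as_weights(conn)
    n = w.shape[0]
    floating = np.flatnonzero(w.sum(axis=1) == 0)
    active = np.setdiff1d(np.arange(n), floating)

    lengths = weight_to_length(w)
    d = all_pairs_shortest_paths(lengths)

    nodal = pd.DataFrame(
        {
            "strength": nodal_strength(w),
            "clustering": clustering_onnela(w),
            "local_efficiency": local_efficiency(w),
            "betweenness": betweenness_centrality(lengths),
            "path_length": nodal_shortest_path_length(d),
            "assortativity": local_assortativity(w),
        }
    )
    if isinstance(conn, Connectome) and conn.atlas is not None:
        nodal.index = conn.atlas.names

    whole: dict = {"n_floating": int(floating.size)}
    if active.size >= 2:
        d_act = d[np.ix_(active, active)]
        cpl, excluded = characteristic_path_length(d_act)
        whole["characteristic_path_length"] = cpl
        whole["excluded_pair_fraction"] = excluded
        whole["global_efficiency"] = global_efficiency(d_act)
    else:
        whole["characteristic_path_length"] = float("nan")
        whole["excluded_pair_fraction"] = float("nan")
        whole["global_efficiency"] = float("nan")
    whole["global_clustering"] = float(nodal["clustering"].iloc[active].mean())
    whole["mean_local_efficiency"] = float(nodal["local_efficiency"].iloc[active].mean())
    whole["global_assortativity"] = global_assortativity(w)
    return nodal, whole
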