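"""Graph metrics on binary undirected networks.

Five quantities are analyzed: average clustering coefficient (Cp), harmonic
mean path length (Lp), modularity Q of a greedy agglomerative partition,
betweenness centrality (BC) and degree. All operate on the 0/1 adjacency of
a :class:`~taunet.network.BinaryNetwork` (a plain symmetric array is also
accepted).

Lp is the reciprocal of the mean inverse shortest-path distance over ordered
node pairs; disconnected pairs contribute an inverse distance of zero, so Lp
stays finite on fragmented graphs.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

log = logging.getLogger(__name__)


def _adj(P) -> np.ndarray:
    A = P.P if hasattr(P, "P") else np.asarray(P)
    return A.astype(float)


def degree(P) -> np.ndarray:
    """Number of edges at each node; sums to 2K."""
    return _adj(P).sum(axis=1).astype(int)


def clustering_coefficient(P) -> float:
    """Mean over nodes of closed-triangle fraction; degree<2 nodes count 0."""
    A = _adj(P)
    N = A.shape[0]
    if N < 3:
        raise ValueError("clustering coefficient needs at least 3 nodes")
    d = A.sum(axis=1)
    if d.sum() == 0:
        log.warning("empty network: clustering coefficient defined as 0")
        return 0.0
    triangles = np.diag(A @ A @ A) / 2.0
    denom = d * (d - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(d >= 2, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean())


def distance_matrix(P) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf if disconnected)."""
    return shortest_path(csr_matrix(_adj(P)), unweighted=True, directed=False)


def harmonic_path_length(P) -> float:
    """Lp = [ mean over ordered pairs i!=j of 1/d_ij ]^-1 (1/inf = 0)."""
    A = _adj(P)
    N = A.shape[0]
    if N < 2:
        raise ValueError("path length needs at least 2 nodes")
    if A.sum() == 0:
        raise ValueError("path length undefined on an edgeless network")
    D = distance_matrix(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(D)] = 0.0
    return float(1.0 / (inv.sum() / (N * (N - 1))))


def betweenness_centrality(P, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness: fractional shortest-path counts over unordered pairs.

    Raw counts by default; with ``normalized=True`` divided by (N-1)(N-2)/2.
    """
    A = _adj(P)
    G = nx.from_numpy_array(A)
    bc = nx.betweenness_centrality(G, normalized=normalized)
    return np.asarray([bc[i] for i in range(A.shape[0])])


def modularity_q(P, membership) -> float:
    """Q = sum_c [e_c/m - (d_c/2m)^2] evaluated on a given partition."""
    A = _adj(P)
    membership = np.asarray(membership)
    m = A.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    q = 0.0
    for c in np.unique(membership):
        mask = membership == c
        e_c = A[np.ix_(mask, mask)].sum() / 2.0
        d_c = A[mask].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def modularity_greedy(P) -> tuple[np.ndarray, float]:
    """Greedy agglomerative modularity maximization.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest modularity gain (ties broken by the
    lexicographically smallest community-index pair), returning the
    membership vector at the maximum Q along the merge path and that Q.
    """
    A = _adj(P)
    N = A.shape[0]
    m = A.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    # B[i, j]: edges between communities i and j; intra: edges inside
    B = A.copy()
    intra = np.zeros(N)
    deg = A.sum(axis=1)
    comms: list[list[int]] = [[i] for i in range(N)]

    def current_q() -> float:
        return float(intra.sum() / m - ((deg / (2 * m)) ** 2).sum())

    best_q = current_q()
    best_comms = [list(c) for c in comms]
    while len(comms) > 1:
        gain = B / m - np.outer(deg, deg) / (2.0 * m * m)
        gain[B == 0] = -np.inf          # only connected pairs may merge
        gain[np.tril_indices(len(comms))] = -np.inf
        flat = int(np.argmax(gain))     # row-major argmax = smallest (i, j) tie-break
        i, j = divmod(flat, len(comms))
        if not np.isfinite(gain[i, j]):
            break                       # disconnected remainder: no legal merge
        intra[i] += intra[j] + B[i, j]
        deg[i] += deg[j]
        B[i, :] += B[j, :]
        B[:, i] += B[:, j]
        B[i, i] = 0.0
        keep = np.arange(len(comms)) != j
        B = B[np.ix_(keep, keep)]
        intra = intra[keep]
        deg = deg[keep]
        comms[i].extend(comms[j])
        del comms[j]
        q = current_q()
        if q > best_q + 1e-12:
            best_q = q
            best_comms = [list(c) for c in comms]
    membership = np.empty(N, dtype=int)
    for label, nodes in enumerate(best_comms):
        membership[nodes] = label
    return membership, best_q


def global_metrics(P) -> dict[str, float]:
    """Cp, Lp and greedy-partition Q for one binary network."""
    return {"cp": clustering_coefficient(P),
            "lp": harmonic_path_length(P),
            "q": modularity_greedy(P)[1]}


def nodal_metrics(P, normalized_bc: bool = False) -> dict[str, np.ndarray]:
    """Per-region betweenness and degree."""
    return {"bc": betweenness_centrality(P, normalized=normalized_bc),
            "degree": degree(P).astype(float)}


def degree_zscore(P) -> np.ndarray:
    """Degree standardized across regions (mean 0, sd 1 within the network)."""
    d = degree(P).astype(float)
    sd = d.std()
    return (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)


def metric_curves(networks: dict, grid) -> pd.DataFrame:
    """Tidy (group, sparsity, metric, value) table of global metrics.

    ``networks`` maps group label -> GroupNetwork; the same sparsity grid is
    applied to every group.
    """
    from .network import binarize_at_sparsity
    rows = []
    for group, net in networks.items():
        for s in grid:
            gm = global_metrics(binarize_at_sparsity(net, float(s)))
            for metric, value in gm.items():
                rows.append({"group": group, "sparsity": float(s),
                             "metric": metric, "value": value})
    return pd.DataFrame(rows)
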