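"""Nodal graph properties of binary undirected networks.

Five voxel-level properties are computed on each link-density network:
degree (hubness), clustering coefficient (segregation), betweenness
centrality (within-network communication), nodal efficiency (integration),
and participation coefficient (diversity of inter-module connections).

Conventions
-----------
* Betweenness is the unnormalized Brandes count of shortest-path fractions;
  pairs in different components contribute nothing.
* Nodal efficiency is E_i = (1/(V-1)) * sum_j 1/d_ij with 1/inf := 0.
* The participation coefficient needs a module partition, which binary-graph
  toolboxes leave to the user; :func:`detect_modules` provides a
  deterministic greedy-modularity partition.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .types import NodalMetricVector, Partition

__all__ = [
    "nodal_degree",
    "clustering_coefficient",
    "betweenness_centrality",
    "nodal_efficiency",
    "detect_modules",
    "participation_coefficient",
    "all_nodal_metrics",
]


def _as_binary(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = (a != 0)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a)):
        raise ValueError("adjacency must have zero diagonal")
    return a


def nodal_degree(adjacency: np.ndarray, density: float = np.nan) -> NodalMetricVector:
    """Number of links incident to each node (row sums)."""
    a = _as_binary(adjacency)
    return NodalMetricVector("D", a.sum(axis=1).astype(float), density)


def clustering_coefficient(adjacency: np.ndarray, density: float = np.nan) -> NodalMetricVector:
    """C_i = 2 t_i / (k_i (k_i - 1)); zero where the degree is below 2.

    t_i is the number of triangles through node i, obtained from the
    diagonal of A^3.
    """
    a = _as_binary(adjacency).astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return NodalMetricVector("CC", c, density)


def betweenness_centrality(adjacency: np.ndarray, density: float = np.nan) -> NodalMetricVector:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    For an undirected graph every unordered pair {s, t} is counted once,
    i.e. the directed Brandes totals are halved.
    """
    a = _as_binary(adjacency)
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source BFS with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        order: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                order.append(v)
                for w in neighbors[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return NodalMetricVector("BC", bc / 2.0, density)


def nodal_efficiency(adjacency: np.ndarray, density: float = np.nan) -> NodalMetricVector:
    """E_i = mean over j != i of 1/d_ij, with unreachable pairs contributing 0."""
    a = _as_binary(adjacency)
    n = a.shape[0]
    if n < 2:
        return NodalMetricVector("E", np.zeros(n), density)
    d = shortest_path(csr_matrix(a.astype(np.int8)), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return NodalMetricVector("E", inv.sum(axis=1) / (n - 1), density)


def modularity(adjacency: np.ndarray, module_id: np.ndarray) -> float:
    """Newman modularity Q of a labeled partition of a binary graph."""
    a = _as_binary(adjacency).astype(float)
    m2 = a.sum()  # 2m
    if m2 == 0:
        raise ValueError("modularity requires at least one edge")
    k = a.sum(axis=1)
    labels = np.asarray(module_id)
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        q += a[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return float(q)


def detect_modules(adjacency: np.ndarray, seed: int = 0) -> Partition:
    """Deterministic greedy modularity-maximization partition.

    Uses the agglomerative fast-greedy algorithm (igraph backend), which is
    deterministic for a given graph; ``seed`` is accepted for interface
    uniformity.  Isolated nodes end up in singleton modules.
    """
    import igraph

    a = _as_binary(adjacency)
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, 1))
    if len(ii) == 0:
        raise ValueError("module detection requires at least one edge")
    g = igraph.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    clustering = g.community_fastgreedy().as_clustering()
    raw = np.asarray(clustering.membership)
    # relabel 1..M in order of first appearance
    _, first_idx = np.unique(raw, return_index=True)
    order = raw[np.sort(first_idx)]
    remap = {int(lab): i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[int(x)] for x in raw])
    return Partition(labels, modularity(a, labels))


def participation_coefficient(
    adjacency: np.ndarray, partition: Partition | np.ndarray, density: float = np.nan
) -> NodalMetricVector:
    """P_i = 1 - sum_m (k_im / k_i)^2; zero for isolated nodes."""
    a = _as_binary(adjacency).astype(float)
    labels = partition.module_id if isinstance(partition, Partition) else np.asarray(partition)
    if len(labels) != a.shape[0]:
        raise ValueError("partition must label every node")
    k = a.sum(axis=1)
    p = np.zeros(a.shape[0])
    for lab in np.unique(labels):
        k_im = a[:, labels == lab].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p += np.where(k > 0, (k_im / np.where(k > 0, k, 1.0)) ** 2, 0.0)
    return NodalMetricVector("PC", np.where(k > 0, 1.0 - p, 0.0), density)


def all_nodal_metrics(
    adjacency: np.ndarray,
    density: float = np.nan,
    partition: Partition | None = None,
    seed: int = 0,
) -> dict[str, NodalMetricVector]:
    """All five nodal metrics of one binary network, keyed by metric name.

    If no partition is supplied one is detected from this network (the
    per-subject mode); pass a fixed partition to evaluate every subject
    against a common module structure.
    """
    a = _as_binary(adjacency)
    if partition is None:
        partition = detect_modules(a, seed=seed)
    return {
        "D": nodal_degree(a, density),
        "BC": betweenness_centrality(a, density),
        "CC": clustering_coefficient(a, density),
        "E": nodal_efficiency(a, density),
        "PC": participation_coefficient(a, partition, density),
    }
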