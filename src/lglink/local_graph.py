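"""Enclosing-subgraph extraction and hop/type node labeling.

For every candidate pair (p, d) the local context is the node-induced
subgraph of the *original* bipartite association graph spanned by the two
core nodes and their h-hop BFS neighborhoods.  The target edge (p, d) is
removed from the extracted subgraph when present, so a model scoring the
pair can never read the very link it is asked to predict.

Nodes carry integer labels encoding entity type and hop stage: the core
A-side node is 0 and the core B-side node is 1; an A-side node at hop i is
labeled 2i and a B-side node at hop i is labeled 2i+1.  The labels, one-hot
encoded, are the initial node features of the local model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocalGraph",
    "bipartite_neighbors",
    "extract_enclosing_subgraph",
    "label_nodes",
    "encode_labels",
]


@dataclass
class LocalGraph:
    """Enclosing subgraph of one candidate pair.

    ``node_ids`` are global indices (A-side nodes are 0..m-1, B-side nodes
    m..m+n-1), sorted ascending; ``edges`` are (i, j) positions into
    ``node_ids`` with i on the A side; ``core_a``/``core_b`` are positions
    of the two core nodes; ``hop`` is the per-node distance to the nearest
    core, computed before target-edge removal.
    """

    node_ids: np.ndarray
    edges: list[tuple[int, int]]
    core_a: int
    core_b: int
    hop: np.ndarray
    m: int
    n: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def is_a_side(self) -> np.ndarray:
        return self.node_ids < self.m

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency of the subgraph (no self loops)."""
        adj = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = 1.0
        return adj


def bipartite_neighbors(A: np.ndarray) -> list[list[int]]:
    """Adjacency lists over global node indices (A side first, then B side)."""
    A = np.asarray(A)
    m, n = A.shape
    nbrs: list[list[int]] = [[] for _ in range(m + n)]
    for p, d in np.argwhere(A == 1):
        nbrs[p].append(m + d)
        nbrs[m + d].append(int(p))
    return nbrs


def _bfs_dists(nbrs: list[list[int]], source: int, max_hops: int) -> dict[int, int]:
    dists = {source: 0}
    frontier = [source]
    for depth in range(1, max_hops + 1):
        nxt: list[int] = []
        for u in frontier:
            for v in nbrs[u]:
                if v not in dists:
                    dists[v] = depth
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return dists


def extract_enclosing_subgraph(
    A: np.ndarray,
    p: int,
    d: int,
    h: int,
    nbrs: list[list[int]] | None = None,
) -> LocalGraph:
    """Extract the h-hop enclosing subgraph of the pair (p, d).

    BFS runs on the original bipartite graph including the target edge (so
    hop distances stay well defined even when that edge is the only
    connection); the target edge is then dropped from the induced edge set.
    A pair of isolated cores yields a valid 2-node, 0-edge subgraph.
    """
    A = np.asarray(A)
    m, n = A.shape
    if h < 1:
        raise ValueError("neighbor order h must be >= 1")
    if not (0 <= p < m and 0 <= d < n):
        raise IndexError(f"pair ({p}, {d}) outside matrix of shape {A.shape}")
    if nbrs is None:
        nbrs = bipartite_neighbors(A)
    d_glob = m + d
    dist_p = _bfs_dists(nbrs, p, h)
    dist_d = _bfs_dists(nbrs, d_glob, h)

    nodes = sorted(set(dist_p) | set(dist_d) | {p, d_glob})
    pos = {v: i for i, v in enumerate(nodes)}
    inf = np.iinfo(np.int64).max
    hop = np.array(
        [min(dist_p.get(v, inf), dist_d.get(v, inf)) for v in nodes], dtype=np.int64
    )
    core_a, core_b = pos[p], pos[d_glob]
    hop[core_a] = 0
    hop[core_b] = 0

    a_nodes = [v for v in nodes if v < m]
    b_nodes = [v for v in nodes if v >= m]
    edges: list[tuple[int, int]] = []
    if a_nodes and b_nodes:
        sub = A[np.ix_(a_nodes, [v - m for v in b_nodes])]
        for ia, ib in np.argwhere(sub == 1):
            u, v = a_nodes[ia], b_nodes[ib]
            if u == p and v == d_glob:
                continue  # remove the target edge: no information leakage
            edges.append((pos[u], pos[v]))
    return LocalGraph(
        node_ids=np.array(nodes, dtype=np.int64),
        edges=edges,
        core_a=core_a,
        core_b=core_b,
        hop=hop,
        m=m,
        n=n,
    )


def label_nodes(local_graph: LocalGraph) -> np.ndarray:
    """Hop/type labels: cores 0 (A side) and 1 (B side); hop-i nodes 2i / 2i+1."""
    hop = local_graph.hop
    if (hop < 0).any():
        raise ValueError("hop map contains undefined (negative) entries")
    a_side = local_graph.is_a_side()
    labels = np.where(a_side, 2 * hop, 2 * hop + 1)
    labels[local_graph.core_a] = 0
    labels[local_graph.core_b] = 1
    return labels.astype(np.int64)


def encode_labels(labels: np.ndarray, h: int) -> np.ndarray:
    """One-hot encode labels into 2h+2 bins; labels beyond the range clamp to the last bin."""
    labels = np.asarray(labels, dtype=np.int64)
    if (labels < 0).any():
        raise ValueError("labels must be non-negative")
    dim = 2 * h + 2
    clamped = np.minimum(labels, dim - 1)
    out = np.zeros((len(labels), dim))
    out[np.arange(len(labels)), clamped] = 1.0
    return out
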