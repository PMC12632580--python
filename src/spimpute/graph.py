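"""k-nearest-neighbor graphs over spatial coordinates.

Graphs are directed (i -> j means j is a neighbor of i), every node has
out-degree exactly k (clamped to n-1), and a self-loop is added for every
node so attention layers can normalize over N(i) ∪ {i}.  Three neighbor
metrics are supported: exact L2, exact inner product, and a seed-pinned
random-projection LSH approximation of L2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["NeighborGraph", "build_knn", "sample_batch_graph"]

METRICS = ("l2", "ip", "lsh")


@dataclass
class NeighborGraph:
    n_nodes: int
    edges: np.ndarray          # (E, 2) int: [src, dst]
    k: int
    metric: str
    includes_self: bool = True

    def neighbor_matrix(self) -> np.ndarray:
        """(n, k+1) index matrix, column 0 the node itself, then its k
        neighbors in rank order.  Requires uniform out-degree (always true
        for graphs built here)."""
        nbrs = np.empty((self.n_nodes, self.k + 1), dtype=np.int64)
        nbrs[:, 0] = np.arange(self.n_nodes)
        mask = self.edges[:, 0] != self.edges[:, 1]
        non_self = self.edges[mask]
        order = np.argsort(non_self[:, 0], kind="stable")
        nbrs[:, 1:] = non_self[order, 1].reshape(self.n_nodes, self.k)
        return nbrs

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t",
                   header="src\tdst", comments="")


def _neighbors_l2(coords: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(coords)
    _, idx = nn.kneighbors(coords)
    return _strip_self(idx, k)


def _neighbors_ip(coords: np.ndarray, k: int) -> np.ndarray:
    sim = coords @ coords.T
    np.fill_diagonal(sim, -np.inf)
    return np.argsort(-sim, axis=1, kind="stable")[:, :k]


def _strip_self(idx: np.ndarray, k: int) -> np.ndarray:
    """Remove each row's own index from a (n, k+1) neighbor table."""
    n = idx.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    rows = np.arange(n)
    for i in rows:
        row = idx[i]
        row = row[row != i][:k]
        if len(row) < k:  # self not in the table (duplicate coordinates)
            row = np.concatenate([row, idx[i, : k - len(row)]])
        out[i] = row
    return out


def _neighbors_lsh(coords: np.ndarray, k: int, n_bits: int = 8,
                   seed: int = 0) -> np.ndarray:
    """Approximate L2 neighbors via sign-random-projection bucketing.

    Candidates share a hash bucket (or one within Hamming distance 1);
    rows with too few candidates fall back to the exact search.
    """
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    n_bits = min(n_bits, max(2, int(np.log2(max(n, 4)))))
    planes = rng.normal(size=(coords.shape[1], n_bits))
    shifts = np.median(coords @ planes, axis=0)
    codes = ((coords @ planes - shifts) > 0).astype(np.uint8)
    keys = codes @ (1 << np.arange(n_bits, dtype=np.uint64))
    buckets: dict = {}
    for i, key in enumerate(keys):
        buckets.setdefault(int(key), []).append(i)
    out = np.empty((n, k), dtype=np.int64)
    flips = 1 << np.arange(n_bits, dtype=np.uint64)
    for i in range(n):
        key = int(keys[i])
        cand = list(buckets.get(key, []))
        for f in flips:
            cand.extend(buckets.get(int(key ^ int(f)), []))
        cand = np.unique([c for c in cand if c != i])
        if len(cand) < k:
            cand = np.setdiff1d(np.arange(n), [i])
        d2 = ((coords[cand] - coords[i]) ** 2).sum(axis=1)
        out[i] = cand[np.argsort(d2, kind="stable")[:k]]
    return out


def build_knn(coords: np.ndarray, k: int, metric: str = "l2",
              include_self: bool = True, lsh_seed: int = 0) -> NeighborGraph:
    """Directed k-NN graph over 2-D coordinates plus self-loops.

    ``k >= n`` is clamped to n-1 with a warning; the single-node case
    yields a self-loop-only graph.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    metric = metric.lower()
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        if n > 1:
            logger.warning("k=%d >= n=%d; clamping to %d", k, n, n - 1)
        k = max(n - 1, 0)
    if k == 0:
        edges = np.asarray([[0, 0]], dtype=np.int64) if include_self else \
            np.empty((0, 2), dtype=np.int64)
        return NeighborGraph(n_nodes=n, edges=edges, k=0, metric=metric,
                             includes_self=include_self)
    if metric == "l2":
        nbrs = _neighbors_l2(coords, k)
    elif metric == "ip":
        nbrs = _neighbors_ip(coords, k)
    else:
        nbrs = _neighbors_lsh(coords, k, seed=lsh_seed)
    src = np.repeat(np.arange(n), k)
    edges = np.column_stack([src, nbrs.ravel()])
    if include_self:
        loops = np.column_stack([np.arange(n), np.arange(n)])
        edges = np.vstack([loops, edges])
    return NeighborGraph(n_nodes=n, edges=edges.astype(np.int64), k=k,
                         metric=metric, includes_self=include_self)


def sample_batch_graph(coords: np.ndarray, batch_ids: Sequence[int], k: int,
                       metric: str = "l2", lsh_seed: int = 0) -> NeighborGraph:
    """k-NN graph recomputed *within* a sampled node set.

    Node i of the returned graph is ``batch_ids[i]``; neighbors are found
    among the sampled cells only, so the subgraph is self-contained for a
    mini-batch.  Deterministic given ``batch_ids``.
    """
    batch_ids = np.asarray(batch_ids, dtype=np.int64)
    if len(np.unique(batch_ids)) != len(batch_ids):
        raise ValueError("batch_ids must be distinct")
    sub = np.asarray(coords, dtype=np.float64)[batch_ids]
    return build_knn(sub, k=k, metric=metric, lsh_seed=lsh_seed)
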