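"""Median-joining haplotype networks (Bandelt, Forster & Röhl 1999).

The network starts from the minimum spanning network (MSN: the union of
all minimum spanning trees, optionally relaxed by a tolerance epsilon)
over the observed haplotypes under weighted Hamming distance, then
iteratively adds *median vectors* — unsampled intermediate haplotypes
formed position-wise from node triplets (majority state where two of
three agree, every state where all differ) — whenever doing so shortens
the minimum spanning tree. Obsolete medians (degree < 3 in the final
MSN) are pruned. Positions carrying any missing state (N/-) are removed
up front (complete deletion) so the distance stays a metric.

Per-position weights default to a uniform 10 (the NETWORK program's
convention); a per-position table can emphasize slowly mutating sites.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .seqio import SeqRecord

__all__ = ["mj_network", "weighted_hamming", "minimum_spanning_network"]

_MISSING = (ord("N"), ord("-"))
DEFAULT_WEIGHT = 10.0


def _to_matrix(haplotypes: Sequence[SeqRecord | str]) -> np.ndarray:
    rows = [
        h.residues if isinstance(h, SeqRecord) else h.upper() for h in haplotypes
    ]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("haplotypes must be aligned")
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


def weighted_hamming(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    return float(w[a != b].sum())


def _pairwise(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = ((M[i] != M) * w).sum(axis=1)
    return D


def minimum_spanning_network(
    D: np.ndarray, epsilon: float = 0.0
) -> list[tuple[int, int]]:
    """Edges of the MSN: Kruskal passes keeping, at each distinct weight
    level, every edge joining two components connectable at that level
    (within epsilon of the minimal connecting weight)."""
    n = D.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    iu = np.triu_indices(n, k=1)
    edges = sorted(
        zip(D[iu], iu[0], iu[1]), key=lambda t: (t[0], t[1], t[2])
    )
    kept: list[tuple[int, int]] = []
    first_level: dict[tuple[int, int], float] = {}
    i = 0
    while i < len(edges):
        d = edges[i][0]
        level = []
        while i < len(edges) and edges[i][0] <= d + 1e-12:
            level.append(edges[i])
            i += 1
        # record the first weight at which each component pair connects
        accepted = []
        for dd, u, v in level:
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            key = (min(ru, rv), max(ru, rv))
            delta = first_level.setdefault(key, dd)
            if dd <= delta + epsilon + 1e-12:
                accepted.append((u, v))
        for u, v in accepted:
            kept.append((u, v))
        for u, v in accepted:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
        first_level.clear()
    return kept


def _mst_weight(D: np.ndarray) -> float:
    """Prim's algorithm MST total weight on a dense matrix."""
    n = D.shape[0]
    if n < 2:
        return 0.0
    in_tree = np.zeros(n, dtype=bool)
    best = D[0].copy()
    in_tree[0] = True
    best[0] = np.inf
    total = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += best[j]
        in_tree[j] = True
        best = np.minimum(best, D[j])
        best[in_tree] = np.inf
    return total


def _quasi_medians(tri: np.ndarray, cap: int = 27) -> list[bytes]:
    """Position-wise (quasi-)medians of a 3-row state matrix."""
    m = tri[0].copy()
    free_cols = []
    for j in range(tri.shape[1]):
        col = tri[:, j]
        if col[0] == col[1] or col[0] == col[2]:
            m[j] = col[0]
        elif col[1] == col[2]:
            m[j] = col[1]
        else:
            free_cols.append(j)  # all three states differ
    if not free_cols:
        return [bytes(m)]
    if 3 ** len(free_cols) > cap:
        return []
    out = []
    for combo in itertools.product(range(3), repeat=len(free_cols)):
        mm = m.copy()
        for j, c in zip(free_cols, combo):
            mm[j] = tri[c, j]
        out.append(bytes(mm))
    return out


def mj_network(
    haplotypes: Sequence[SeqRecord | str],
    counts: Sequence[int] | None = None,
    weights: Sequence[float] | Mapping[int, float] | None = None,
    epsilon: float = 0.0,
) -> nx.Graph:
    """Median-joining network over pre-collapsed haplotypes.

    Returns a networkx Graph whose nodes carry attributes `seq`, `count`
    (0 for inferred medians) and `median` (bool), and whose edges carry
    `n_mut` (number of differing positions), `positions` (their 0-based
    column indices after missing-column removal) and `cost` (weighted
    distance). Raises on duplicate input haplotypes.
    """
    M_full = _to_matrix(haplotypes)
    n_obs, L_full = M_full.shape
    if n_obs < 2:
        raise ValueError("need >= 2 haplotypes")
    if counts is None:
        counts = [1] * n_obs
    if len(counts) != n_obs:
        raise ValueError("counts length mismatch")

    keep = ~np.isin(M_full, _MISSING).any(axis=0)  # complete deletion
    M = M_full[:, keep]
    if weights is None:
        w = np.full(M.shape[1], DEFAULT_WEIGHT)
    elif isinstance(weights, Mapping):
        w = np.array([weights.get(j, DEFAULT_WEIGHT) for j in np.where(keep)[0]])
    else:
        w = np.asarray(weights, dtype=float)[keep]
    if (w <= 0).any():
        raise ValueError("weights must be positive")

    seqs = [bytes(row) for row in M]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate haplotypes: collapse before building the network")

    names = [
        h.id if isinstance(h, SeqRecord) else f"H{i + 1}" for i, h in enumerate(haplotypes)
    ]
    node_seqs: list[bytes] = list(seqs)
    node_names: list[str] = list(names)
    node_counts: list[int] = list(counts)
    is_median: list[bool] = [False] * n_obs

    def matrix() -> np.ndarray:
        return np.array([np.frombuffer(s, dtype=np.uint8) for s in node_seqs])

    n_medians = 0
    while True:
        Mat = matrix()
        D = _pairwise(Mat, w)
        base_cost = _mst_weight(D)
        msn = minimum_spanning_network(D, epsilon)
        G = nx.Graph()
        G.add_nodes_from(range(len(node_seqs)))
        G.add_edges_from(msn)
        # candidate medians from triples with at least two MSN links
        cand: dict[bytes, float] = {}
        existing = set(node_seqs)
        for u in G.nodes:
            nbrs = sorted(G.neighbors(u))
            for a, b in itertools.combinations(nbrs, 2):
                tri = Mat[[u, a, b]]
                for m in _quasi_medians(tri):
                    if m in existing or m in cand:
                        continue
                    mv = np.frombuffer(m, dtype=np.uint8)
                    dcol = ((Mat != mv) * w).sum(axis=1)
                    Daug = np.zeros((D.shape[0] + 1, D.shape[0] + 1))
                    Daug[:-1, :-1] = D
                    Daug[-1, :-1] = dcol
                    Daug[:-1, -1] = dcol
                    cand[m] = _mst_weight(Daug)
        best_m, best_cost = None, base_cost - 1e-9
        for m, c in sorted(cand.items()):
            if c < best_cost:
                best_m, best_cost = m, c
        if best_m is None:
            break
        n_medians += 1
        node_seqs.append(best_m)
        node_names.append(f"mv{n_medians}")
        node_counts.append(0)
        is_median.append(True)

    # prune obsolete medians (degree < 3 in the final MSN)
    while True:
        Mat = matrix()
        D = _pairwise(Mat, w)
        msn = minimum_spanning_network(D, epsilon)
        deg = {i: 0 for i in range(len(node_seqs))}
        for u, v in msn:
            deg[u] += 1
            deg[v] += 1
        drop = [
            i for i in range(len(node_seqs)) if is_median[i] and deg[i] < 3
        ]
        if not drop:
            break
        for i in sorted(drop, reverse=True):
            del node_seqs[i], node_names[i], node_counts[i], is_median[i]

    Mat = matrix()
    D = _pairwise(Mat, w)
    msn = minimum_spanning_network(D, epsilon)
    net = nx.Graph()
    for i, name in enumerate(node_names):
        net.add_node(
            name,
            seq=node_seqs[i].decode(),
            count=node_counts[i],
            median=is_median[i],
        )
    for u, v in msn:
        diff_cols = np.where(Mat[u] != Mat[v])[0]
        net.add_edge(
            node_names[u],
            node_names[v],
            n_mut=int(diff_cols.size),
            positions=[int(c) for c in diff_cols],
            cost=float(w[diff_cols].sum()),
        )
    return net
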