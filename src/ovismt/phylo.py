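"""Tamura-Nei (1993) distances, neighbor-joining and bootstrap support.

TN93 distinguishes the two transition types (A<->G within purines,
C<->T within pyrimidines) from transversions and uses empirical base
frequencies. With transition proportions P1 (A/G), P2 (C/T), transversion
proportion Q, purine/pyrimidine frequencies gR = gA+gG, gY = gC+gT and

    k1 = 2 gA gG / gR,   k2 = 2 gT gC / gY,
    k3 = 2 (gR gY - gA gG gY/gR - gT gC gR/gY),

the distance is

    d = -k1 ln w1 - k2 ln w2 - k3 ln w3
    w1 = 1 - P1/k1 - Q/(2 gR)
    w2 = 1 - P2/k2 - Q/(2 gY)
    w3 = 1 - Q/(2 gR gY)

(no rate heterogeneity). A non-positive logarithm argument means the
pair is saturated; the distance is reported infinite.

Neighbor-joining delegates the Saitou-Nei/Studier-Keppler agglomeration
to scikit-bio; taxa are sorted lexicographically first so ties resolve
deterministically, and negative branch lengths are clamped to zero.
Bootstrap support resamples alignment columns, rebuilds the tree, and
counts how often each original bipartition recurs.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .seqio import SeqRecord

__all__ = [
    "tn93_distance",
    "tn93_matrix",
    "base_frequencies",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
]

_MISSING = (ord("N"), ord("-"))


def _to_arrays(seqs: Sequence[SeqRecord | str]) -> tuple[list[str], np.ndarray]:
    ids = [
        s.id if isinstance(s, SeqRecord) else f"t{i}" for i, s in enumerate(seqs)
    ]
    rows = [s.residues if isinstance(s, SeqRecord) else s.upper() for s in seqs]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("sequences must be aligned")
    M = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    return ids, M


def base_frequencies(seqs: Sequence[SeqRecord | str]) -> dict[str, float]:
    """Empirical ACGT frequencies pooled over all sequences."""
    _, M = _to_arrays(seqs)
    counts = {b: int((M == ord(b)).sum()) for b in "ACGT"}
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError("no unambiguous bases")
    return {b: c / tot for b, c in counts.items()}


def _pair_props(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, int]:
    valid = ~(
        np.isin(a, _MISSING) | np.isin(b, _MISSING)
    )
    a, b = a[valid], b[valid]
    L = a.size
    if L == 0:
        raise ValueError("no overlapping non-missing sites")
    diff = a != b
    isA, isG = a == ord("A"), a == ord("G")
    isC, isT = a == ord("C"), a == ord("T")
    bA, bG = b == ord("A"), b == ord("G")
    bC, bT = b == ord("C"), b == ord("T")
    p1 = ((isA & bG) | (isG & bA)).sum() / L
    p2 = ((isC & bT) | (isT & bC)).sum() / L
    q = diff.sum() / L - p1 - p2
    return float(p1), float(p2), float(q), L


def tn93_distance(
    seq_a: SeqRecord | str,
    seq_b: SeqRecord | str,
    base_freqs: Mapping[str, float],
) -> float:
    """TN93 maximum-likelihood distance for one aligned pair.

    base_freqs should come from the pooled data (`base_frequencies`).
    Returns inf (saturation) when a logarithm argument is non-positive.
    """
    a = np.frombuffer(
        (seq_a.residues if isinstance(seq_a, SeqRecord) else seq_a.upper()).encode(),
        dtype=np.uint8,
    )
    b = np.frombuffer(
        (seq_b.residues if isinstance(seq_b, SeqRecord) else seq_b.upper()).encode(),
        dtype=np.uint8,
    )
    if a.size != b.size:
        raise ValueError("pair must be aligned")
    p1, p2, q, _ = _pair_props(a, b)
    gA, gC, gG, gT = (base_freqs[x] for x in "ACGT")
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - p2 / k2 - q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.inf
    d = 0.0
    if k1 > 0:
        d -= k1 * np.log(w1)
    if k2 > 0:
        d -= k2 * np.log(w2)
    d -= k3 * np.log(w3)
    return float(max(d, 0.0))


def tn93_matrix(seqs: Sequence[SeqRecord | str]) -> DistanceMatrix:
    """Pairwise TN93 distances with pooled empirical base frequencies."""
    ids, M = _to_arrays(seqs)
    freqs = base_frequencies(seqs)
    n = len(ids)
    D = np.zeros((n, n))
    recs = [s if isinstance(s, str) else s.residues for s in seqs]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_distance(recs[i], recs[j], freqs)
    if np.isinf(D).any():
        warnings.warn("saturated pairs: infinite TN93 distances present")
    return DistanceMatrix(D, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree with non-negative branch lengths.

    Taxa are sorted lexicographically before agglomeration so that tied
    Q-criterion choices resolve deterministically regardless of input
    order.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor-joining needs >= 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return tree


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each encoded as the side holding the smallest taxon."""
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue  # trivial split
        canonical = side if anchor in side else taxa - side
        splits.add(canonical)
    return splits


def bootstrap_support(
    seqs: Sequence[SeqRecord],
    n_reps: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Bootstrap percentages for the bipartitions of the full-data NJ tree.

    Columns are resampled with replacement; each replicate alignment is
    run through the same TN93 + NJ pipeline. Support is the percentage of
    replicates whose tree contains the original bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, M = _to_arrays(seqs)
    if M.shape[1] < 2:
        raise ValueError("alignment too short to bootstrap")
    ref_tree = nj_tree(tn93_matrix(seqs))
    ref_splits = tree_bipartitions(ref_tree)
    hits = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(M.shape[1], size=M.shape[1])
        boot = [
            SeqRecord(ids[i], bytes(M[i, cols]).decode()) for i in range(len(ids))
        ]
        try:
            splits = tree_bipartitions(nj_tree(tn93_matrix(boot)))
        except (ValueError, ZeroDivisionError):
            continue  # saturated / degenerate replicate carries no votes
        for s in ref_splits:
            if s in splits:
                hits[s] += 1
    return {s: 100.0 * h / n_reps for s, h in hits.items()}
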