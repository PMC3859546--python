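"""Haplotype collapsing and standard within/between-group diversity.

Statistics follow Nei (1987):

* haplotype (gene) diversity  h = n (1 - sum p_i^2) / (n - 1), with
  sampling variance (Nei 1987, eq. 8.12)
      V(h) = 2 / (n(n-1)) * { 2(n-2) [ sum p_i^3 - (sum p_i^2)^2 ]
                              + sum p_i^2 - (sum p_i^2)^2 }
* nucleotide diversity per site  pi = sum_{i<j} d_ij / C(n,2) / Lbar,
  with d_ij the pairwise difference count under pairwise deletion and
  Lbar the mean compared length; variance from Nei (1987, eq. 10.7):
      V(pi) = (n+1) pi / (3(n-1) L) + 2 (n^2+n+3) pi^2 / (9 n (n-1))
* between-group divergence  Dxy = mean per-site differences over all
  cross-group pairs.

Missing data ('N' and '-') are excluded pairwise (pairwise deletion),
matching common population-genetics software behaviour for this kind of
data. Sites where either sequence of a pair is missing contribute to
neither the difference count nor the compared length of that pair.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .seqio import SeqRecord

__all__ = [
    "HaplotypeTable",
    "DiversityStats",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "dxy",
    "pairwise_diff_matrix",
]

_MISSING = frozenset(b"N-")


def _as_matrix(seqs: Sequence[SeqRecord | str]) -> np.ndarray:
    rows = [s.residues if isinstance(s, SeqRecord) else s.upper() for s in seqs]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("sequences must be aligned (equal length)")
    return np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])


def _valid_mask(M: np.ndarray) -> np.ndarray:
    return (M != ord("N")) & (M != ord("-"))


def pairwise_diff_matrix(
    seqs: Sequence[SeqRecord | str],
) -> tuple[np.ndarray, np.ndarray]:
    """(differences, compared-length) matrices under pairwise deletion."""
    M = _as_matrix(seqs)
    V = _valid_mask(M)
    n = M.shape[0]
    D = np.zeros((n, n), dtype=np.int64)
    L = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = V[i] & V
        D[i] = ((M[i] != M) & both).sum(axis=1)
        L[i] = both.sum(axis=1)
    return D, L


@dataclasses.dataclass
class HaplotypeTable:
    """Distinct haplotypes with their multiplicities."""

    haplotypes: list[str]
    counts: list[int]
    n: int
    L: int
    members: list[list[int]] = dataclasses.field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.haplotypes)


@dataclasses.dataclass
class DiversityStats:
    n: int
    k: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


def collapse_haplotypes(seqs: Sequence[SeqRecord | str]) -> HaplotypeTable:
    """Merge sequences identical at all mutually non-missing sites.

    Pairwise-deletion identity is not transitive in general; merging is
    greedy in input order (each sequence joins the first established
    haplotype it is indistinguishable from), which matches how sequences
    with sporadic missing data are binned in practice.
    """
    if len(seqs) == 0:
        raise ValueError("no sequences")
    M = _as_matrix(seqs)
    V = _valid_mask(M)
    reps: list[int] = []
    members: list[list[int]] = []
    for i in range(M.shape[0]):
        placed = False
        for g, r in enumerate(reps):
            both = V[i] & V[r]
            if not ((M[i] != M[r]) & both).any():
                members[g].append(i)
                placed = True
                break
        if not placed:
            reps.append(i)
            members.append([i])
    def _name(i: int) -> str:
        s = seqs[i]
        return s.residues if isinstance(s, SeqRecord) else s
    return HaplotypeTable(
        haplotypes=[_name(r) for r in reps],
        counts=[len(m) for m in members],
        n=M.shape[0],
        L=M.shape[1],
        members=members,
    )


def haplotype_diversity(tab: HaplotypeTable) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation."""
    n = tab.n
    if n < 2:
        raise ValueError("need n >= 2 for haplotype diversity")
    p = np.asarray(tab.counts, dtype=float) / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(seqs: Sequence[SeqRecord | str]) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard deviation."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2 for nucleotide diversity")
    D, L = pairwise_diff_matrix(seqs)
    iu = np.triu_indices(n, k=1)
    lbar = float(L[iu].mean())
    if lbar == 0:
        raise ValueError("no mutually compared sites")
    pi = float(D[iu].sum() / len(iu[0]) / lbar)
    var = (n + 1) * pi / (3.0 * (n - 1) * lbar) + 2.0 * (
        n**2 + n + 3
    ) * pi**2 / (9.0 * n * (n - 1))
    return pi, float(np.sqrt(max(var, 0.0)))


def diversity_stats(seqs: Sequence[SeqRecord | str]) -> DiversityStats:
    """The Table-1-style summary for one group of aligned sequences."""
    tab = collapse_haplotypes(seqs)
    h, h_sd = haplotype_diversity(tab)
    pi, pi_sd = nucleotide_diversity(seqs)
    return DiversityStats(tab.n, tab.k, h, h_sd, pi, pi_sd)


def dxy(
    group_x: Sequence[SeqRecord | str], group_y: Sequence[SeqRecord | str]
) -> float:
    """Average per-site divergence over all cross-group pairs."""
    if len(group_x) == 0 or len(group_y) == 0:
        raise ValueError("both groups must be non-empty")
    allseq = list(group_x) + list(group_y)
    D, L = pairwise_diff_matrix(allseq)
    nx = len(group_x)
    cross_d = D[:nx, nx:]
    cross_l = L[:nx, nx:]
    lbar = float(cross_l.mean())
    if lbar == 0:
        raise ValueError("no mutually compared sites between groups")
    return float(cross_d.sum() / cross_d.size / lbar)
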