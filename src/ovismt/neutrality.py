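"""Tajima's D and Fu's Fs with coalescent-simulation p-values.

Tajima's D (Tajima 1989) contrasts the mean pairwise difference count
theta_pi with Watterson's S/a1:

    D = (theta_pi - S/a1) / sqrt(e1 S + e2 S (S-1))

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2. D is
undefined (not zero) when S = 0.

Fu's Fs (Fu 1997) asks how surprising the observed haplotype count k_obs
is under the Ewens sampling formula at theta = theta_pi:

    S' = P(K >= k_obs | theta) =
         sum_{k >= k_obs} |s(n,k)| theta^k / (theta (theta+1) ... (theta+n-1))

with |s(n,k)| the unsigned Stirling numbers of the first kind, and
Fs = ln(S' / (1 - S')). Computation is in log space so n up to a few
hundred is exact to floating precision.

p-values follow the simulation approach of the standard software: neutral
constant-size coalescent replicates conditioned on n (theta = S/a1 for D,
theta = theta_pi for Fs); D uses an equal-tail two-sided p, Fs the
conventional left tail P(Fs_sim <= Fs_obs).
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from . import coalescent as _coal
from .diversity import pairwise_diff_matrix, _as_matrix, _valid_mask, collapse_haplotypes
from .seqio import SeqRecord

__all__ = [
    "NeutralityResult",
    "tajimas_d",
    "fus_fs",
    "fs_from_k",
    "segregating_sites",
    "theta_pi_abs",
]


@dataclasses.dataclass
class NeutralityResult:
    statistic_name: str
    value: float | None
    p_value: float | None
    n: int
    S: int
    theta_pi: float


def segregating_sites(seqs: Sequence[SeqRecord | str]) -> int:
    """Sites with >= 2 distinct non-missing bases."""
    M = _as_matrix(seqs)
    V = _valid_mask(M)
    S = 0
    for j in range(M.shape[1]):
        col = M[V[:, j], j]
        if col.size and (col != col[0]).any():
            S += 1
    return S


def theta_pi_abs(seqs: Sequence[SeqRecord | str]) -> float:
    """Mean pairwise difference count (absolute, not per site)."""
    D, _ = pairwise_diff_matrix(seqs)
    iu = np.triu_indices(len(seqs), k=1)
    return float(D[iu].mean())


def _tajima_constants(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajima_d_from_counts(n: int, S: int, theta_pi: float) -> float | None:
    if S == 0:
        return None
    a1 = float((1.0 / np.arange(1, n)).sum())
    e1, e2 = _tajima_constants(n)
    return float((theta_pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))


def tajimas_d(
    seqs: Sequence[SeqRecord | str],
    n_reps: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Tajima's D with a two-sided coalescent-simulation p-value.

    Replicates are neutral constant-size samples of the same n with theta
    set to the Watterson estimate S/a1; the p-value is the equal-tail
    two-sided rank of the observed D among simulated D (with the +1
    finite-sample correction; replicates with S=0 are dropped).
    """
    n = len(seqs)
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    S = segregating_sites(seqs)
    tp = theta_pi_abs(seqs)
    d = _tajima_d_from_counts(n, S, tp)
    if d is None:
        return NeutralityResult("TajimaD", None, None, n, S, tp)
    a1 = float((1.0 / np.arange(1, n)).sum())
    theta_w = S / a1
    rng = np.random.default_rng(seed)
    dem = _coal.DemographySpec("constant", theta_w, n=n)
    sims = []
    for _ in range(n_reps):
        S_s, tp_s, _ = _coal.sim_summary(dem, rng)
        d_s = _tajima_d_from_counts(n, S_s, tp_s)
        if d_s is not None:
            sims.append(d_s)
    sims_arr = np.asarray(sims)
    r = sims_arr.size
    p_le = (1 + (sims_arr <= d).sum()) / (r + 1)
    p_ge = (1 + (sims_arr >= d).sum()) / (r + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return NeutralityResult("TajimaD", d, float(p), n, S, tp)


@lru_cache(maxsize=8)
def _log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (log 0 = -inf)."""
    cur = np.full(n + 1, -np.inf)
    cur[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):  # |s(m+1,k)| = m |s(m,k)| + |s(m,k-1)|
        nxt = np.full(n + 1, -np.inf)
        scaled = cur[1:] + np.log(m) if m > 0 else np.full(n, -np.inf)
        nxt[1:] = np.logaddexp(scaled, cur[:-1])
        cur = nxt
    return cur


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = _log_stirling_first(n)
    k = np.arange(n + 1)
    log_rising = gammaln(theta + n) - gammaln(theta)
    return ls + k * np.log(theta) - log_rising


def fs_from_k(n: int, theta: float, k_obs: int) -> float | None:
    """Fu's Fs from sample size, theta-hat and observed haplotype count.

    Returns None at the k_obs = 1 boundary (S' = 1, Fs undefined).
    """
    if k_obs <= 1:
        return None
    logp = ewens_log_pmf(n, theta)
    log_sp = logsumexp(logp[k_obs:])
    # log(1 - S') computed from the complementary tail for stability
    log_one_minus = logsumexp(logp[:k_obs])
    return float(log_sp - log_one_minus)


def fus_fs(
    seqs: Sequence[SeqRecord | str],
    n_reps: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Fu's Fs with a left-tail coalescent-simulation p-value.

    theta-hat is the mean pairwise difference count (Fu's choice);
    haplotypes are counted with the same pairwise-deletion collapsing
    rules as the diversity module. Replicates keep theta fixed at the
    observed theta-hat and evaluate each simulated sample's Fs at its own
    pairwise-difference estimate; p = P(Fs_sim <= Fs_obs).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2")
    S = segregating_sites(seqs)
    tp = theta_pi_abs(seqs)
    if tp == 0:
        return NeutralityResult("FuFs", None, None, n, S, tp)
    k_obs = collapse_haplotypes(seqs).k
    fs = fs_from_k(n, tp, k_obs)
    if fs is None:
        return NeutralityResult("FuFs", None, None, n, S, tp)
    rng = np.random.default_rng(seed)
    dem = _coal.DemographySpec("constant", tp, n=n)
    count_le = 0
    r = 0
    for _ in range(n_reps):
        _, tp_s, k_s = _coal.sim_summary(dem, rng)
        if tp_s == 0 or k_s <= 1:
            fs_s = np.inf  # no expansion signal at all
        else:
            fs_s = fs_from_k(n, tp_s, k_s)
        r += 1
        if fs_s <= fs:
            count_le += 1
    p = (1 + count_le) / (r + 1)
    return NeutralityResult("FuFs", fs, float(p), n, S, tp)
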