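"""Kingman coalescent simulator with infinite-sites mutation.

Time is measured in *pairwise mutational units*: the unit is chosen so that
the expected number of differences between two sequences drawn from an
equilibrium population of scaled size theta equals theta (theta = 2Nu for a
haploid/maternally inherited locus such as mtDNA, with N females and u the
per-sequence per-generation mutation rate). Concretely, on this clock

* each lineage mutates at rate 1/2 per unit time, and
* k lineages coalesce at rate C(k,2) / theta(s),

so E[pairwise differences] = theta at equilibrium and E[S] = a1 * theta
with a1 = sum_{i=1}^{n-1} 1/i (Watterson).

The sudden-expansion demography is an instantaneous size change looking
backward: scaled size theta1 (post-expansion, present) for s < tau and
theta0 (pre-expansion) for s >= tau, where tau = 2ut is the expansion age
in the same pairwise mutational units — so a fitted mismatch tau is
directly comparable to the generator's tau.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["DemographySpec", "Genealogy", "sim_genealogy", "sim_summary", "sim_mismatch_counts"]


@dataclasses.dataclass
class DemographySpec:
    """Demographic model for the coalescent generator.

    model: "constant" (size theta0 throughout; tau ignored) or
    "sudden_expansion" (theta1 until tau backward in time, theta0 before).
    n is the sample size and L the number of sites available to the
    infinite-sites mutation process.
    """

    model: str
    theta0: float
    theta1: float = 0.0
    tau: float = 0.0
    n: int = 0
    L: int = 1000

    def __post_init__(self) -> None:
        if self.model not in ("constant", "sudden_expansion"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be > 0")
        if self.model == "sudden_expansion":
            if self.theta1 <= 0:
                raise ValueError("theta1 must be > 0")
            if self.tau < 0:
                raise ValueError("tau must be >= 0")


@dataclasses.dataclass
class Genealogy:
    """Branches of a realized coalescent tree.

    lengths[b] is the duration of branch b (pairwise mutational units) and
    carriers[b] the boolean leaf-membership vector below it. mutations[b]
    is filled by the mutation-dropping step.
    """

    n: int
    lengths: np.ndarray
    carriers: np.ndarray  # (n_branches, n) bool
    mutations: np.ndarray | None = None


def sim_genealogy(dem: DemographySpec, rng: np.random.Generator) -> Genealogy:
    """Simulate one coalescent genealogy under the given demography."""
    n = dem.n
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if dem.model == "constant":
        theta0 = theta1 = dem.theta0
        tau = np.inf
    else:
        theta0, theta1, tau = dem.theta0, dem.theta1, dem.tau

    # active lineages: birth time + carrier bitset
    births = [0.0] * n
    carriers = [np.zeros(n, dtype=bool) for _ in range(n)]
    for i in range(n):
        carriers[i][i] = True

    out_len: list[float] = []
    out_car: list[np.ndarray] = []
    s = 0.0
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        if s < tau:
            w = rng.exponential(theta1 / rate)
            if s + w >= tau:
                w = (tau - s) + rng.exponential(theta0 / rate)
        else:
            w = rng.exponential(theta0 / rate)
        s += w
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        out_len.append(s - births[i])
        out_car.append(carriers[i])
        out_len.append(s - births[j])
        out_car.append(carriers[j])
        merged = carriers[i] | carriers[j]
        # replace i, remove j
        births[i] = s
        carriers[i] = merged
        del births[j], carriers[j]
        k -= 1
    return Genealogy(n, np.array(out_len), np.array(out_car))


def drop_mutations(gen: Genealogy, rng: np.random.Generator) -> Genealogy:
    """Poisson mutations on branches at rate 1/2 per unit branch length."""
    gen.mutations = rng.poisson(gen.lengths / 2.0)
    return gen


def sim_summary(dem: DemographySpec, rng: np.random.Generator) -> tuple[int, float, int]:
    """One replicate's (S, theta_pi, k_haplotypes) without building sequences.

    S counts mutations on branches (infinite sites: every mutation is a new
    segregating site). theta_pi is the mean pairwise difference count.
    Haplotypes are distinct leaf mutation signatures.
    """
    gen = drop_mutations(sim_genealogy(dem, rng), rng)
    m = gen.mutations
    hit = m > 0
    n = gen.n
    if not hit.any():
        return 0, 0.0, 1
    sizes = gen.carriers[hit].sum(axis=1)
    mm = m[hit]
    S = int(mm.sum())
    pairs = n * (n - 1) / 2.0
    theta_pi = float((mm * sizes * (n - sizes)).sum() / pairs)
    # leaves with identical membership across mutated branches share a haplotype
    sig = gen.carriers[hit].repeat(mm, axis=0)  # one row per mutation
    k = np.unique(sig.T, axis=0).shape[0]
    return S, theta_pi, k


def sim_mismatch_counts(dem: DemographySpec, rng: np.random.Generator) -> np.ndarray:
    """Pairwise-difference matrix (n x n) of one replicate."""
    gen = drop_mutations(sim_genealogy(dem, rng), rng)
    n = gen.n
    D = np.zeros((n, n), dtype=np.int64)
    hit = gen.mutations > 0
    for mb, x in zip(gen.mutations[hit], gen.carriers[hit]):
        split = x[:, None] ^ x[None, :]
        D += int(mb) * split
    return D


def genealogy_sequences(
    gen: Genealogy,
    rng: np.random.Generator,
    L: int,
    ancestral: str | None = None,
) -> list[str]:
    """Realize sequences of length L from a mutated genealogy.

    Each mutation occupies a distinct column (infinite sites) and
    substitutes a different base for its carriers. The ancestral sequence
    is uniform-random over ACGT unless supplied (pass the same `ancestral`
    to several groups to simulate them against a common background, e.g.
    for between-group divergence). Raises ValueError when L cannot host
    the realized mutation count.
    """
    if gen.mutations is None:
        raise ValueError("genealogy has no mutations dropped")
    total = int(gen.mutations.sum())
    if total > L:
        raise ValueError(
            f"{total} mutations exceed sequence length L={L}; increase L"
        )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    if ancestral is not None:
        if len(ancestral) != L:
            raise ValueError("ancestral sequence length must equal L")
        anc = np.frombuffer(ancestral.upper().encode(), dtype=np.uint8).copy()
    else:
        anc = rng.choice(bases, size=L)
    seqs = np.tile(anc, (gen.n, 1))
    cols = rng.choice(L, size=total, replace=False)
    ci = 0
    hit = gen.mutations > 0
    for mb, x in zip(gen.mutations[hit], gen.carriers[hit]):
        for _ in range(int(mb)):
            col = cols[ci]
            ci += 1
            # derived base: any base different from the carriers' current state
            cur = seqs[np.argmax(x), col]
            seqs[x, col] = rng.choice(bases[bases != cur])
    return ["".join(chr(c) for c in row) for row in seqs]
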