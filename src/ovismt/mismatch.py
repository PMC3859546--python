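"""Mismatch distributions and the sudden-expansion model.

The observed mismatch distribution is the histogram of pairwise
difference counts over all unordered sequence pairs (pairwise deletion
for missing data). Its mean equals theta_pi exactly — the identity behind
"mean mismatch tracks within-group nucleotide diversity".

The sudden-expansion model: a population at scaled size theta0 grows
instantaneously to theta1 at tau pairwise-mutational units before the
present (tau = 2ut). The pairwise difference count j is Poisson-mixed
over the pair's coalescence time, whose hazard is 1/theta1 until tau and
1/theta0 beyond, giving the closed form

    F_j = Fhat_j(theta1) * P(j+1, tau (1+theta1)/theta1)
        + exp(tau (1/theta0 - 1/theta1)) * Fhat_j(theta0)
          * Q(j+1, tau (1+theta0)/theta0)

where Fhat_j(theta) = theta^j / (1+theta)^{j+1} is the equilibrium
(geometric) distribution and P/Q are the regularized lower/upper
incomplete gamma functions. At tau=0 this collapses to Fhat(theta0)
(the expansion has just happened; all pairwise coalescences predate it)
and for theta0=theta1 to the equilibrium at that theta. The form is
validated against the coalescent simulator rather than trusted on paper.

Fitting minimizes the sum of squared deviations (SSD) between observed
and model frequencies over classes 0..j_max; the goodness-of-fit p-value
is a parametric bootstrap: simulate under the fitted model, refit each
replicate, and count SSDs at least as large as observed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaincc

from . import coalescent as _coal
from .diversity import pairwise_diff_matrix
from .seqio import SeqRecord

__all__ = [
    "MismatchDistribution",
    "MismatchFit",
    "observed_mismatch",
    "expected_mismatch",
    "fit_expansion",
    "ssd_test",
]

_THETA1_CAP_FACTOR = 1e5  # cap theta1 at 1e5 * mean to kill the flat ridge


@dataclasses.dataclass
class MismatchDistribution:
    """Relative frequencies f_j of pairwise difference count j = 0..j_max."""

    freqs: np.ndarray
    n_pairs: int
    n: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def mean(self) -> float:
        return float((np.arange(self.freqs.size) * self.freqs).sum())


@dataclasses.dataclass
class MismatchFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float | None = None
    n_boot: int = 0


def observed_mismatch(seqs: Sequence[SeqRecord | str]) -> MismatchDistribution:
    """Histogram of pairwise differences over all unordered pairs."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2")
    D, _ = pairwise_diff_matrix(seqs)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    counts = np.bincount(d)
    return MismatchDistribution(counts / counts.sum(), n_pairs=d.size, n=n)


def _counts_to_mismatch(D: np.ndarray) -> MismatchDistribution:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    counts = np.bincount(d)
    return MismatchDistribution(counts / counts.sum(), n_pairs=d.size, n=n)


def equilibrium_mismatch(theta: float, j_max: int) -> np.ndarray:
    """Fhat_j(theta) = theta^j / (1+theta)^{j+1}, j = 0..j_max."""
    j = np.arange(j_max + 1)
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta)) if theta > 0 else (
        np.eye(1, j_max + 1, 0).ravel()
    )


def expected_mismatch(
    tau: float, theta0: float, theta1: float, j_max: int
) -> np.ndarray:
    """Model mismatch probabilities, renormalized over 0..j_max."""
    for name, v in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if theta0 < 0 or theta1 <= 0 or tau < 0:
        raise ValueError("parameters must be positive (tau >= 0)")
    j = np.arange(j_max + 1)
    recent = equilibrium_mismatch(theta1, j_max) * gammainc(
        j + 1, tau * (1.0 + theta1) / theta1
    )
    if theta0 > 0 and (theta0 == 0 or tau / theta0 < 500.0):
        ancient = (
            np.exp(tau * (1.0 / theta0 - 1.0 / theta1))
            * equilibrium_mismatch(theta0, j_max)
            * gammaincc(j + 1, tau * (1.0 + theta0) / theta0)
        )
    else:  # theta0 -> 0 limit: surviving pairs coalesce at tau, j ~ Poisson(tau)
        from scipy.stats import poisson

        ancient = np.exp(-tau / theta1) * poisson.pmf(j, tau)
    f = recent + ancient
    s = f.sum()
    if s <= 0:
        raise ValueError("degenerate model distribution")
    return f / s


def _ssd(params: np.ndarray, obs: np.ndarray) -> float:
    tau, th0, th1 = params
    if tau < 0 or th0 < 0 or th1 <= 1e-9 or th0 > th1:
        return np.inf
    exp_f = expected_mismatch(tau, max(th0, 1e-9), th1, obs.size - 1)
    return float(((obs - exp_f) ** 2).sum())


def _ssd_unconstrained(x: np.ndarray, obs: np.ndarray) -> float:
    # smooth reparameterization: tau=x0^2, theta0=x1^2, theta1=x1^2+x2^2
    tau, th0, dth = x[0] ** 2, x[1] ** 2, x[2] ** 2
    return _ssd(np.array([tau, th0, th0 + dth + 1e-9]), obs)


def fit_expansion(obs: MismatchDistribution) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch.

    Grid initialization (tau over [0, 2*mean], theta0 over [0, mean],
    theta1 in {10, 100, 1000} * mean) followed by Nelder-Mead refinement;
    theta0 <= theta1 is enforced, theta1 capped at 1e5 * mean.
    Deterministic given the input.
    """
    f = obs.freqs
    nz = (f > 0).sum()
    mean = obs.mean
    if nz < 2 or mean == 0:
        warnings.warn("degenerate mismatch distribution: tau=0 boundary fit")
        return MismatchFit(0.0, 0.0, max(mean, 1e-6), ssd=_ssd_safe(f, 0.0, 0.0, max(mean, 1e-6)))
    best = None
    taus = np.linspace(0.0, 2.0 * mean, 7)
    th0s = np.linspace(0.0, mean, 4)
    th1s = mean * np.array([10.0, 100.0, 1000.0])
    for t in taus:
        for a in th0s:
            for b in th1s:
                s = _ssd(np.array([t, a, b]), f)
                if best is None or s < best[0]:
                    best = (s, np.array([t, a, b]))
    gt, g0, g1 = best[1]
    x0 = np.sqrt([gt, max(g0, mean / 20.0), max(g1 - g0, 1e-3)])
    res = minimize(
        _ssd_unconstrained,
        x0,
        args=(f,),
        method="Powell",
        options={"xtol": 1e-8, "ftol": 1e-12, "maxiter": 60, "maxfev": 320},
    )
    tau, th0 = res.x[0] ** 2, res.x[1] ** 2
    th1 = th0 + res.x[2] ** 2 + 1e-9
    th1 = min(th1, _THETA1_CAP_FACTOR * mean)
    th0 = min(th0, th1)
    return MismatchFit(float(tau), float(th0), float(th1), ssd=float(_ssd(np.array([tau, th0, th1]), f)))


def _ssd_safe(f: np.ndarray, tau: float, th0: float, th1: float) -> float:
    try:
        return float(((f - expected_mismatch(tau, th0, th1, f.size - 1)) ** 2).sum())
    except ValueError:
        return np.inf


def ssd_test(
    obs: MismatchDistribution,
    fit: MismatchFit,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap goodness-of-fit p for the sudden-expansion model.

    Simulates n_boot coalescent datasets of the same sample size under the
    fitted (tau, theta0, theta1), refits each, and returns the fraction
    whose refitted SSD is >= the observed SSD. Seeded and bit-reproducible.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives an unstable p; use >= 100")
    if obs.n < 2:
        raise ValueError("observed distribution lacks its sample size n")
    rng = np.random.default_rng(seed)
    th0 = max(fit.theta0, 1e-6)
    dem = _coal.DemographySpec(
        "sudden_expansion", theta0=th0, theta1=max(fit.theta1, th0), tau=fit.tau, n=obs.n
    )
    count_ge = 0
    for _ in range(n_boot):
        D = _coal.sim_mismatch_counts(dem, rng)
        sim = _counts_to_mismatch(D)
        sim_fit = fit_expansion(sim)
        if sim_fit.ssd >= fit.ssd:
            count_ge += 1
    return count_ge / n_boot
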