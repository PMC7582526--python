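"""Random-prediction null model for top-T interface-pair hit counts.

If T residue pairs are drawn at random from the N inter-chain pairs of one
interface, of which M are true interface pairs, the number of true pairs
among the T drawn follows the hypergeometric distribution H(N, M, T).
Treating the three interfaces of a trimer as i.i.d. copies, the
probability that at least z of the three interfaces receive at least one
true pair in their top-T list has a closed form in

    p1 = P(X >= 1) = 1 - C(N-M, T) / C(N, T).

Exact values (``exact``):

    z=1: p1          z=2: 3 p1^2 (1-p1) + p1^3          z=3: p1^3

Alongside the exact forms this module reports the widely quoted simplified
closed forms (``bound``):

    q       = (N - M - T + 1) / (N - T + 1)
    bhat1   = 1 - q
    bhat2   = 1 - 3 q^2 + 2 ((N - M) / N)^3
    bhat3   = (1 - q)^3

Note: ``bhat1`` replaces the product of T depletion ratios by its single
smallest factor, i.e. it is a *single-draw-style approximation*. For
T >= 2 it is smaller than the exact probability (the correct upper bound
would exponentiate: 1 - q**T >= p1); the exact forms are authoritative and
the approximations are provided for comparability with published practice.
All three are monotone in T and M and are reported both as probabilities
and as percent strings with 4 significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "NullParams",
    "NullProbabilities",
    "hypergeom_pmf",
    "p1",
    "p2",
    "p3",
    "null_probabilities",
    "trimer_null_exact",
    "monte_carlo_null",
    "percent",
]


@dataclass(frozen=True)
class NullParams:
    """N total pairs per interface, M positives among them, T top-list size."""

    N: int
    M: int
    T: int

    def __post_init__(self) -> None:
        if not 0 <= self.M <= self.N:
            raise ValueError(f"require 0 <= M <= N, got M={self.M}, N={self.N}")
        if not 1 <= self.T <= self.N:
            raise ValueError(f"require 1 <= T <= N, got T={self.T}, N={self.N}")


@dataclass(frozen=True)
class NullProbabilities:
    """Exact probabilities and closed-form approximations for z = 1, 2, 3."""

    exact1: float
    exact2: float
    exact3: float
    bound1: float
    bound2: float
    bound3: float

    def as_percent(self) -> dict[str, str]:
        # z=1 quantities are customarily quoted with 5 significant figures,
        # the much smaller z=2/3 ones with 4
        return {
            "exact1": percent(self.exact1, 5), "bound1": percent(self.bound1, 5),
            "exact2": percent(self.exact2), "bound2": percent(self.bound2),
            "exact3": percent(self.exact3), "bound3": percent(self.bound3),
        }


def percent(p: float, sig: int = 4) -> str:
    """Render a probability as a percent string with ``sig`` significant figures."""
    x = p * 100.0
    if x == 0:
        return "0%"
    from math import floor, log10

    digits = sig - 1 - floor(log10(abs(x)))
    return f"{round(x, digits):.{max(digits, 0)}f}%"


def hypergeom_pmf(params: NullParams, x: int) -> float:
    """P(X = x) for X ~ H(N, M, T); zero outside the support."""
    # scipy's convention: hypergeom(M=N_total, n=n_success, N=n_draws)
    return float(hypergeom.pmf(x, params.N, params.M, params.T))


def _p1_exact(params: NullParams) -> float:
    N, M, T = params.N, params.M, params.T
    if T > N - M:
        return 1.0
    # 1 - C(N-M,T)/C(N,T) via the survival function of H at 0
    return float(1.0 - hypergeom.pmf(0, N, M, T))


def p1(params: NullParams) -> tuple[float, float]:
    """(exact, closed-form approximation) for >=1 hit on one interface."""
    N, M, T = params.N, params.M, params.T
    exact = _p1_exact(params)
    bound = 1.0 - (N - M - T + 1) / (N - T + 1)
    return exact, bound


def p2(params: NullParams) -> tuple[float, float]:
    """(exact, closed-form approximation) for >=2 of 3 interfaces hit."""
    N, M, T = params.N, params.M, params.T
    e1 = _p1_exact(params)
    exact = 3.0 * e1**2 * (1.0 - e1) + e1**3
    q = (N - M - T + 1) / (N - T + 1)
    bound = 1.0 - 3.0 * q**2 + 2.0 * ((N - M) / N) ** 3
    return exact, bound


def p3(params: NullParams) -> tuple[float, float]:
    """(exact, closed-form approximation) for all 3 interfaces hit."""
    N, M, T = params.N, params.M, params.T
    e1 = _p1_exact(params)
    q = (N - M - T + 1) / (N - T + 1)
    return e1**3, (1.0 - q) ** 3


def null_probabilities(params: NullParams) -> NullProbabilities:
    e1, b1 = p1(params)
    e2, b2 = p2(params)
    e3, b3 = p3(params)
    return NullProbabilities(e1, e2, e3, b1, b2, b3)


def trimer_null_exact(params: NullParams, z: int) -> float:
    """Exact P(L0 >= z): at least z of 3 i.i.d. interfaces get >= 1 hit.

    For z = 2 and z = 3 this coincides with the ``exact`` values of
    :func:`p2` / :func:`p3`. For z = 1 it is ``1 - (1 - p1)**3`` — note
    the widely quoted per-interface probability ``p1`` itself is *not*
    a trimer-level event probability (it understates P(L0 >= 1) by about
    a factor of 3 when small); this function is the correct closed form
    for what a Monte-Carlo simulation of three interfaces estimates.
    """
    if z not in (1, 2, 3):
        raise ValueError(f"z must be 1, 2 or 3, got {z}")
    e1 = _p1_exact(params)
    if z == 1:
        return 1.0 - (1.0 - e1) ** 3
    if z == 2:
        return 3.0 * e1**2 * (1.0 - e1) + e1**3
    return e1**3


def monte_carlo_null(
    params: NullParams,
    z: int,
    n_draws: int,
    seed: int | None = None,
    chunk: int = 1_000_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(at least z of 3 interfaces get >=1 hit).

    Simulates three independent H(N, M, T) hit counts per draw and returns
    (frequency, binomial standard error). Exact degenerate cases (M=0, or
    M=N with T>=1) return (0, 0) / (1, 0) without sampling noise only in
    the sense that every draw gives the same outcome.
    """
    if z not in (1, 2, 3):
        raise ValueError(f"z must be 1, 2 or 3, got {z}")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    N, M, T = params.N, params.M, params.T
    hits = 0
    remaining = n_draws
    while remaining > 0:
        size = min(chunk, remaining)
        counts = rng.hypergeometric(M, N - M, T, size=(size, 3))
        hits += int(((counts > 0).sum(axis=1) >= z).sum())
        remaining -= size
    p = hits / n_draws
    se = float(np.sqrt(p * (1.0 - p) / n_draws))
    return p, se
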