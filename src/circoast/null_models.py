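"""Closed-form models of random cell placement.

The binomial model of random placement (BMRP) treats each cell's
colocalization as an independent Bernoulli(p) event with p = CDNF, so the
colocalized count c out of n cells is Binomial(n, p).  The single-image
colocalization test reports the upper-tail probability P(X >= c) of
observing at least the seen number of colocalized cells under random
placement.

The hypergeometric model (HMRP) accounts for the finite number of
non-overlapping cells an image can hold: with N = A·η / (π r²) placeable
cells (η the Monte-Carlo packing ratio) of which K = N·p would colocalize,
the observed count is Hypergeometric(N, K, n).  It is provided for model
comparison; the binomial model is the one used for hypothesis testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .imaging import CdnfValue, CellModel, ColocObservation
from .placement_sim import PackingTable


@dataclass(frozen=True)
class DistributionMoments:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class HypergeomParams:
    """Finite-population parameters: N placeable cells, K of them colocalizing."""

    N_max: int
    K_coloc: int

    def __post_init__(self) -> None:
        if not 0 <= self.K_coloc <= self.N_max:
            raise ValueError("need 0 <= K_coloc <= N_max")


def _check_binom(c: int, n: int, p: float) -> None:
    if not 0 <= c <= n:
        raise ValueError(f"need 0 <= c <= n, got c={c}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")


def _log_binom_pmf(c, n: int, p: float):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)
                + np.where(c > 0, c * np.log(p), 0.0)
                + np.where(n - c > 0, (n - c) * np.log1p(-p), 0.0))
    return logp


def binomial_pmf(c: int, n: int, p: float) -> float:
    """P(X = c) for X ~ Binomial(n, p), computed in log space."""
    _check_binom(c, n, p)
    if p == 0.0:
        return 1.0 if c == 0 else 0.0
    if p == 1.0:
        return 1.0 if c == n else 0.0
    return float(np.exp(_log_binom_pmf(c, n, p)))


def binomial_moments(n: int, p: float) -> DistributionMoments:
    """Mean n·p and standard deviation sqrt(n·p·(1−p))."""
    _check_binom(0, n, p)
    return DistributionMoments(n * p, math.sqrt(n * p * (1.0 - p)))


def circoast_image_p(obs: ColocObservation, p: CdnfValue | float) -> float:
    """Single-image colocalization p-value: P(X >= c) under Binomial(n, CDNF).

    The upper tail is computed as a direct log-space sum of pmf terms from c
    to n (not as 1 − CDF, which cancels catastrophically for small tails).
    c = 0 returns exactly 1.
    """
    pv = p.p if isinstance(p, CdnfValue) else float(p)
    if obs.n == 0:
        raise ValueError("no cells sampled: the colocalization test is "
                         "undefined for n = 0")
    _check_binom(obs.c, obs.n, pv)
    if obs.c == 0:
        return 1.0
    if pv == 0.0:
        return 0.0
    if pv == 1.0:
        return 1.0
    ks = np.arange(obs.c, obs.n + 1)
    return float(min(1.0, np.exp(logsumexp(_log_binom_pmf(ks, obs.n, pv)))))


def _check_hypergeom(k: int, N: int, n: int, K: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N, got N={N}, n={n}, K={K}")
    if not (max(0, n - (N - K)) <= k <= min(n, K)):
        raise ValueError(f"k={k} outside support for N={N}, n={n}, K={K}")


def hypergeom_pmf(k: int, N: int, n: int, K: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n): C(K,k)·C(N−K,n−k)/C(N,n)."""
    _check_hypergeom(k, N, n, K)

    def logc(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return float(np.exp(logc(K, k) + logc(N - K, n - k) - logc(N, n)))


def hypergeom_moments(N: int, n: int, K: int) -> DistributionMoments:
    """Mean n·K/N and sd sqrt(n·K·(N−K)·(N−n)/(N²·(N−1))).

    N = 1 implies a census of a single cell; sd is 0 by convention.
    """
    if not (0 <= K <= N and 0 <= n <= N and N >= 1):
        raise ValueError("invalid hypergeometric parameters")
    mean = n * K / N
    if N == 1:
        return DistributionMoments(mean, 0.0)
    var = n * K * (N - K) * (N - n) / (N * N * (N - 1))
    return DistributionMoments(mean, math.sqrt(var))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def hmrp_params(width: int, height: int, cell: CellModel, p: CdnfValue | float,
                table: PackingTable, interpolate: bool = False) -> HypergeomParams:
    """Hypergeometric population parameters from the packing table.

    N = round(A·η / (π r²)) is the maximum number of non-overlapping fully
    contained cells; K = round(N·p) the colocalizing members of that maximal
    population.  Rounds half away from zero (fractional cell counts are
    meaningless for the pmf); K is clamped to [0, N].
    """
    if cell.diameter < 5:
        raise ValueError("HMRP requires cell diameter >= 5 px")
    pv = p.p if isinstance(p, CdnfValue) else float(p)
    eta = table.lookup(cell.diameter, width, height, interpolate=interpolate)
    area = width * height
    N = _round_half_away(area * eta / (math.pi * cell.radius ** 2))
    K = min(max(_round_half_away(N * pv), 0), N)
    return HypergeomParams(N, K)
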