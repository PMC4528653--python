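"""Closed-form solution for a single delayed unimolecular reaction.

For ``N`` independent walkers each undergoing ``S0 -> S1`` with exponential
initiation rate ``k`` and delay PDF ``tau``, the state distribution at any
time is multinomial over (still at source, arrived at product, in flight)
with event probabilities

    p_source(t)   = 1 - F(t)          F(t) = 1 - e^(-k t)
    p_product(t)  = T(t)              T = CDF of the Exp(k) (+) delay sum
    p_inflight(t) = F(t) - T(t)

independently of the delay law's shape.  With zero delay ``T = F`` and the
multinomial collapses to a binomial with parameters ``N`` and ``e^(-k t)``;
with a constant delay ``s``, ``T(t) = 1 - e^(-k (t - s))`` for ``t >= s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .delays import DelayDistribution, compound_cdf_T
from .errors import DcmeError, ParameterError

__all__ = ["EventProbabilities", "event_probabilities", "multinomial_pmf", "solution_table",
           "SolutionTable"]

#: refuse dense (N+1)x(N+1) tables beyond this many cells
MAX_TABLE_CELLS = 2 * 10**8


@dataclass(frozen=True)
class EventProbabilities:
    """The three multinomial cell probabilities at time ``t``."""

    t: float
    p_source: float
    p_product: float
    p_inflight: float

    def as_tuple(self) -> tuple:
        return (self.p_source, self.p_product, self.p_inflight)


def event_probabilities(t: float, k: float, delay: DelayDistribution) -> EventProbabilities:
    if t < 0:
        raise ParameterError("t must be non-negative")
    if k <= 0:
        raise ParameterError("k must be positive")
    F = 1.0 - np.exp(-k * t)
    T = float(compound_cdf_T(t, k, delay))
    T = min(T, F)  # T <= F pointwise; guard quadrature round-off
    return EventProbabilities(t=float(t), p_source=1.0 - F, p_product=T, p_inflight=F - T)


def multinomial_pmf(
    n_source: int, m_product: int, t: float, N: int, k: float, delay: DelayDistribution
) -> float:
    """Probability of ``n`` walkers at the source and ``m`` at the product at time t.

    ``P = N! / (n! m! (N-n-m)!) * (1-F)^n * T^m * (F-T)^(N-n-m)``.
    """
    if n_source < 0 or m_product < 0 or n_source + m_product > N:
        raise ParameterError("need n, m >= 0 with n + m <= N")
    ep = event_probabilities(t, k, delay)
    return _log_multinomial(
        np.array([n_source]), np.array([m_product]), N, ep
    )[0]


def _log_multinomial(n, m, N, ep: EventProbabilities) -> np.ndarray:
    l = N - n - m
    logp = special.gammaln(N + 1) - special.gammaln(n + 1) - special.gammaln(m + 1) \
        - special.gammaln(l + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        for cnt, p in ((n, ep.p_source), (m, ep.p_product), (l, ep.p_inflight)):
            term = np.where(cnt > 0, cnt * np.log(p) if p > 0 else -np.inf, 0.0)
            logp = logp + term
    return np.exp(logp)


@dataclass
class SolutionTable:
    """Dense multinomial solution over ``{(n, m): n + m <= N}`` at one time."""

    t: float
    N: int
    probabilities: np.ndarray  # (N+1, N+1), zero where n + m > N
    event_probs: EventProbabilities

    @property
    def mean_source(self) -> float:
        return self.N * self.event_probs.p_source

    @property
    def mean_product(self) -> float:
        return self.N * self.event_probs.p_product

    def marginal_source(self) -> np.ndarray:
        """Binomial(N, 1 - F) marginal over the source count."""
        return stats.binom.pmf(np.arange(self.N + 1), self.N, self.event_probs.p_source)

    def marginal_product(self) -> np.ndarray:
        """Binomial(N, T) marginal over the product count."""
        return stats.binom.pmf(np.arange(self.N + 1), self.N, self.event_probs.p_product)

    def as_dict(self) -> dict:
        out = {}
        for n in range(self.N + 1):
            for m in range(self.N + 1 - n):
                p = self.probabilities[n, m]
                if p > 0.0:
                    out[(n, m)] = float(p)
        return out


def solution_table(t: float, N: int, k: float, delay: DelayDistribution) -> SolutionTable:
    """Evaluate the full multinomial table at time ``t`` for ``N`` walkers.

    Factorials are taken in log space, so tables remain usable up to
    ``N ~ 10^4`` (bounded by :data:`MAX_TABLE_CELLS`).
    """
    if int(N) != N or N < 1:
        raise ParameterError("N must be a positive integer")
    N = int(N)
    if (N + 1) ** 2 > MAX_TABLE_CELLS:
        raise DcmeError(f"dense table for N={N} exceeds the configured cell cap")
    ep = event_probabilities(t, k, delay)
    n = np.arange(N + 1)[:, None]
    m = np.arange(N + 1)[None, :]
    valid = n + m <= N
    probs = np.zeros((N + 1, N + 1))
    probs[valid] = _log_multinomial(
        np.broadcast_to(n, valid.shape)[valid],
        np.broadcast_to(m, valid.shape)[valid],
        N, ep,
    )
    return SolutionTable(t=float(t), N=N, probabilities=probs, event_probs=ep)
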