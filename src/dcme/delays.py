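"""Delay-distribution algebra for delayed reaction kinetics.

A delayed reaction completes a random time after it is initiated.  When a
linear chain of irreversible unimolecular conversions is lumped into a single
delayed reaction, the delay law is the first-passage time through the chain:
the convolution of the per-step exponential waiting times.  For identical
step rates this is an Erlang distribution; for distinct rates it is a
hypoexponential.  This module provides those laws in closed form, generic
tabulated delays, numerical PDF convolution, the compound CDF ``T(t)`` of an
exponential initiation time plus an independent delay draw, the probability
that a walker traverses a chain before a competing degradation removes it,
and exact sampling from every family.

All distributions expose ``pdf``, ``cdf``, ``sample`` and ``mean``; the CDFs
satisfy the minimal requirements of a delay law: non-decreasing,
right-continuous, with limits 0 at ``t=0^-`` and 1 at infinity.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import integrate, special

from .errors import AccuracyError, GridError, ParameterError

__all__ = [
    "DelayDistribution",
    "erlang_pdf",
    "erlang_cdf",
    "hypoexp_pdf",
    "hypoexp_cdf",
    "compound_cdf_T",
    "arrival_probability",
    "convolve_pdfs",
    "sample_delay",
]

#: default number of grid points used when a distribution has to be tabulated
_NUMERIC_GRID_SIZE = 4096


def _check_erlang_params(r: int, beta: float) -> None:
    if int(r) != r or r < 1:
        raise ParameterError(f"Erlang shape must be a positive integer, got {r}")
    if beta <= 0:
        raise ParameterError(f"Erlang rate must be positive, got {beta}")


def erlang_pdf(t, r: int, beta: float):
    """Erlang(r, beta) density: ``beta^r t^(r-1) e^(-beta t) / (r-1)!`` for t >= 0.

    This is the first-passage density through a chain of ``r`` identical
    exponential steps of rate ``beta`` (the convolution of ``r`` exponential
    densities).
    """
    _check_erlang_params(r, beta)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # log-space to stay finite for large r
    logf = r * math.log(beta) + (r - 1) * np.log(tp) - beta * tp - special.gammaln(r)
    out[pos] = np.exp(logf)
    if r == 1:
        out = np.where(t == 0, beta, out)
    return out if out.ndim else float(out)


def erlang_cdf(t, r: int, beta: float):
    """Erlang(r, beta) CDF: ``1 - e^(-beta t) * sum_{j=0}^{r-1} (beta t)^j / j!``."""
    _check_erlang_params(r, beta)
    t = np.asarray(t, dtype=float)
    out = special.gammainc(r, beta * np.maximum(t, 0.0))
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def _hypoexp_weights(rates: np.ndarray) -> np.ndarray:
    # partial-fraction coefficients w_i = prod_{j != i} lam_j / (lam_j - lam_i)
    lam = np.asarray(rates, dtype=float)
    n = lam.size
    w = np.empty(n)
    for i in range(n):
        others = np.delete(lam, i)
        w[i] = np.prod(others / (others - lam[i]))
    return w


def hypoexp_pdf(t, rates: Sequence[float]):
    """Hypoexponential density (sum of independent exponentials, distinct rates).

    Uses the partial-fraction form ``f(t) = sum_i w_i lam_i e^(-lam_i t)`` with
    ``w_i = prod_{j != i} lam_j / (lam_j - lam_i)``.  Rates must be distinct;
    repeated rates are handled by the Erlang branch or numerically in
    :class:`DelayDistribution`.
    """
    lam = np.asarray(rates, dtype=float)
    if lam.size == 0 or np.any(lam <= 0):
        raise ParameterError("hypoexponential rates must be positive")
    if lam.size == 1:
        return erlang_pdf(t, 1, float(lam[0]))
    if np.min(np.abs(np.subtract.outer(lam, lam)) + np.eye(lam.size)) < 1e-12 * np.max(lam):
        raise ParameterError("hypoexp_pdf requires distinct rates")
    w = _hypoexp_weights(lam)
    t = np.asarray(t, dtype=float)
    out = np.where(
        t[..., None] >= 0, w * lam * np.exp(-lam * np.maximum(t[..., None], 0.0)), 0.0
    ).sum(axis=-1)
    return out if np.ndim(out) else float(out)


def hypoexp_cdf(t, rates: Sequence[float]):
    """Hypoexponential CDF for distinct rates: ``1 - sum_i w_i e^(-lam_i t)``."""
    lam = np.asarray(rates, dtype=float)
    if lam.size == 1:
        return erlang_cdf(t, 1, float(lam[0]))
    w = _hypoexp_weights(lam)
    t = np.asarray(t, dtype=float)
    out = 1.0 - (w * np.exp(-lam * np.maximum(t[..., None], 0.0))).sum(axis=-1)
    out = np.where(t < 0, 0.0, np.clip(out, 0.0, 1.0))
    return out if np.ndim(out) else float(out)


class DelayDistribution:
    """A delay law: zero, constant, Erlang, hypoexponential or tabulated.

    Construct through the classmethods :meth:`zero`, :meth:`constant`,
    :meth:`erlang`, :meth:`hypoexponential` or :meth:`tabulated`.  The zero
    family is the Dirac mass at 0 (no delay); the constant family is the
    Dirac mass at ``s``.
    """

    FAMILIES = ("zero", "constant", "erlang", "hypoexponential", "tabulated")

    def __init__(self, family: str, **params):
        if family not in self.FAMILIES:
            raise ParameterError(f"unknown delay family {family!r}")
        self.family = family
        self.params = params

    # ------------------------------------------------------------------ ctors
    @classmethod
    def zero(cls) -> "DelayDistribution":
        return cls("zero")

    @classmethod
    def constant(cls, s: float) -> "DelayDistribution":
        if s < 0:
            raise ParameterError("constant delay must be >= 0")
        return cls("constant", s=float(s))

    @classmethod
    def erlang(cls, shape: int, rate: float) -> "DelayDistribution":
        _check_erlang_params(shape, rate)
        return cls("erlang", shape=int(shape), rate=float(rate))

    @classmethod
    def hypoexponential(cls, rates: Sequence[float]) -> "DelayDistribution":
        lam = np.asarray(rates, dtype=float)
        if lam.size == 0 or np.any(lam <= 0):
            raise ParameterError("hypoexponential rates must be positive")
        self = cls("hypoexponential", rates=lam.copy())
        self._mode = _hypoexp_mode(lam)
        if self._mode == "numeric":
            self._tab = _tabulate_hypoexp(lam)
        return self

    @classmethod
    def tabulated(cls, grid: Sequence[float], density: Sequence[float]) -> "DelayDistribution":
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or grid.shape != density.shape:
            raise ParameterError("tabulated delay needs matching 1-d grid and density")
        steps = np.diff(grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
            raise GridError("tabulated delay requires a strictly increasing uniform grid")
        if np.any(density < 0):
            raise ParameterError("tabulated density must be non-negative")
        cdf = integrate.cumulative_trapezoid(density, grid, initial=0.0)
        mass = cdf[-1]
        if not 0 < mass:
            raise ParameterError("tabulated density has zero mass")
        self = cls("tabulated", grid=grid.copy(), density=density.copy())
        self._cdf_grid = cdf / mass
        self._mass = mass
        return self

    # ------------------------------------------------------------------- laws
    def pdf(self, t):
        """Density at ``t``.  The zero/constant families are atoms: the density
        is returned as ``inf`` exactly at the atom and 0 elsewhere."""
        f = self.family
        t_arr = np.asarray(t, dtype=float)
        if f == "zero":
            out = np.where(t_arr == 0.0, np.inf, 0.0)
        elif f == "constant":
            out = np.where(t_arr == self.params["s"], np.inf, 0.0)
        elif f == "erlang":
            return erlang_pdf(t, self.params["shape"], self.params["rate"])
        elif f == "hypoexponential":
            lam = self.params["rates"]
            if self._mode == "erlang":
                return erlang_pdf(t, lam.size, float(lam[0]))
            if self._mode == "distinct":
                return hypoexp_pdf(t, lam)
            return self._tab.pdf(t)
        else:  # tabulated
            out = np.interp(t_arr, self.params["grid"], self.params["density"] / self._mass,
                            left=0.0, right=0.0)
        return out if np.ndim(out) else float(out)

    def cdf(self, t):
        f = self.family
        t_arr = np.asarray(t, dtype=float)
        if f == "zero":
            out = np.where(t_arr >= 0.0, 1.0, 0.0)
        elif f == "constant":
            out = np.where(t_arr >= self.params["s"], 1.0, 0.0)
        elif f == "erlang":
            return erlang_cdf(t, self.params["shape"], self.params["rate"])
        elif f == "hypoexponential":
            lam = self.params["rates"]
            if self._mode == "erlang":
                return erlang_cdf(t, lam.size, float(lam[0]))
            if self._mode == "distinct":
                return hypoexp_cdf(t, lam)
            return self._tab.cdf(t)
        else:
            out = np.interp(t_arr, self.params["grid"], self._cdf_grid, left=0.0, right=1.0)
        return out if np.ndim(out) else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        """Exact draw(s) from the delay law using the supplied generator."""
        f = self.family
        if f == "zero":
            return 0.0 if size is None else np.zeros(size)
        if f == "constant":
            s = self.params["s"]
            return s if size is None else np.full(size, s)
        if f == "erlang":
            return rng.gamma(self.params["shape"], 1.0 / self.params["rate"], size=size)
        if f == "hypoexponential":
            lam = self.params["rates"]
            draws = rng.exponential(1.0 / lam, size=(lam.size,) if size is None else (size, lam.size))
            out = draws.sum(axis=-1)
            return float(out) if size is None else out
        # tabulated: inverse-CDF interpolation on the grid
        u = rng.random(size)
        return np.interp(u, self._cdf_grid, self.params["grid"])

    def mean(self) -> float:
        f = self.family
        if f == "zero":
            return 0.0
        if f == "constant":
            return self.params["s"]
        if f == "erlang":
            return self.params["shape"] / self.params["rate"]
        if f == "hypoexponential":
            return float(np.sum(1.0 / self.params["rates"]))
        g, d = self.params["grid"], self.params["density"]
        return float(np.trapezoid(g * d, g) / self._mass)

    # ----------------------------------------------------------------- helpers
    def __eq__(self, other):
        if not isinstance(other, DelayDistribution):
            return NotImplemented
        if self.family != other.family:
            return False
        for key, val in self.params.items():
            ov = other.params.get(key)
            if isinstance(val, np.ndarray):
                if not np.array_equal(val, ov):
                    return False
            elif val != ov:
                return False
        return True

    def __repr__(self):
        items = ", ".join(f"{k}={v}" for k, v in self.params.items())
        return f"DelayDistribution({self.family}, {items})"


def _hypoexp_mode(rates: np.ndarray) -> str:
    scale = np.max(rates)
    if np.allclose(rates, rates[0], rtol=1e-12):
        return "erlang"
    gaps = np.abs(np.subtract.outer(rates, rates)) + scale * np.eye(rates.size)
    if np.min(gaps) > 1e-9 * scale:
        return "distinct"
    return "numeric"  # mixed multiplicities: fall back to tabulated convolution


def _tabulate_hypoexp(rates: np.ndarray) -> "DelayDistribution":
    mean = np.sum(1.0 / rates)
    sd = math.sqrt(np.sum(1.0 / rates**2))
    t_max = mean + 12.0 * sd
    grid = np.linspace(0.0, t_max, _NUMERIC_GRID_SIZE)
    pdfs = [erlang_pdf(grid, 1, lam) for lam in rates]
    conv = convolve_pdfs(pdfs, grid)
    return DelayDistribution.tabulated(grid, conv)


def convolve_pdfs(pdfs: Sequence[np.ndarray], grid: np.ndarray) -> np.ndarray:
    """Iterated discrete convolution of densities on a shared uniform grid.

    Uses trapezoid end-point weights (O(dt^2) accurate for smooth densities),
    rescaled by the grid step so the result integrates to the product of the
    input masses; truncated to the input grid length.
    """
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
        raise GridError("convolve_pdfs requires a uniform increasing grid")
    dt = float(steps[0])
    pdfs = [np.asarray(p, dtype=float) for p in pdfs]
    if not pdfs:
        raise ParameterError("need at least one density")
    for p in pdfs:
        if p.shape != grid.shape:
            raise ParameterError("all densities must live on the supplied grid")
        if np.any(p < 0):
            raise ParameterError("densities must be non-negative")
    out = pdfs[0]
    for p in pdfs[1:]:
        # trapezoid correction: halve the two end-point contributions
        full = np.convolve(out, p)[: grid.size]
        out = (full - 0.5 * (out[0] * p + p[0] * out)) * dt
        np.maximum(out, 0.0, out=out)
    return out


def compound_cdf_T(t, k: float, delay: DelayDistribution):
    """CDF ``T(t)`` of an Exp(k) initiation time plus an independent delay draw.

    This is the CDF of the density ``k e^(-k t) * tau(t)`` (convolution), the
    probability that a walker that starts waiting at time 0 has both initiated
    and completed its delayed transition by time ``t``.  Closed forms are used
    for the zero, constant and matching-rate Erlang cases and for distinct-rate
    hypoexponential combinations; anything else is evaluated by adaptive
    quadrature of ``int_0^t k e^(-k s) C_delay(t - s) ds``.
    """
    if k <= 0:
        raise ParameterError("initiation rate k must be positive")
    f = delay.family
    t_arr = np.asarray(t, dtype=float)
    if f == "zero":
        out = np.where(t_arr >= 0, 1.0 - np.exp(-k * np.maximum(t_arr, 0.0)), 0.0)
        return out if np.ndim(out) else float(out)
    if f == "constant":
        s = delay.params["s"]
        shifted = np.maximum(t_arr - s, 0.0)
        out = np.where(t_arr >= s, 1.0 - np.exp(-k * shifted), 0.0)
        return out if np.ndim(out) else float(out)
    if f == "erlang":
        r, beta = delay.params["shape"], delay.params["rate"]
        if math.isclose(beta, k, rel_tol=1e-12):
            return erlang_cdf(t, r + 1, k)
        if r == 1:
            return hypoexp_cdf(t, [k, beta])
        return _compound_cdf_numeric(t_arr, k, delay)
    if f == "hypoexponential":
        lam = np.concatenate([[k], delay.params["rates"]])
        if _hypoexp_mode(lam) == "distinct":
            return hypoexp_cdf(t, lam)
        return _compound_cdf_numeric(t_arr, k, delay)
    return _compound_cdf_numeric(t_arr, k, delay)


def _compound_cdf_numeric(t_arr: np.ndarray, k: float, delay: DelayDistribution):
    scalar = t_arr.ndim == 0
    flat = np.atleast_1d(t_arr)
    out = np.empty_like(flat, dtype=float)
    for i, ti in enumerate(flat):
        if ti <= 0:
            out[i] = 0.0
            continue
        val, err = integrate.quad(
            lambda s: k * math.exp(-k * s) * delay.cdf(ti - s),
            0.0, ti, epsabs=1e-11, epsrel=1e-10, limit=400,
        )
        if err > 1e-7:
            raise AccuracyError(f"compound CDF quadrature error {err:.2e} at t={ti}")
        out[i] = min(max(val, 0.0), 1.0)
    return float(out[0]) if scalar else out.reshape(t_arr.shape)


def arrival_probability(step_rates: Sequence[float], eigen_magnitudes: Sequence[float]) -> float:
    """Probability that a chain walker reaches the final state before degradation.

    For a maturation chain with forward step rates ``k_i`` and per-step
    removal, the arrival probability is ``prod(k_i) / prod(lambda_k)`` where
    the ``lambda_k`` are the absolute eigenvalues of the chain's transition
    matrix (``k_i + mu_i`` for a bidiagonal chain).  Equal rates give
    ``(k / (k + mu))^r``.
    """
    ks = np.asarray(step_rates, dtype=float)
    lams = np.asarray(eigen_magnitudes, dtype=float)
    if ks.shape != lams.shape or ks.ndim != 1 or ks.size == 0:
        raise ParameterError("step rates and eigenvalue magnitudes must be equal-length lists")
    if np.any(ks <= 0) or np.any(lams <= 0):
        raise ParameterError("rates and eigenvalue magnitudes must be positive")
    return float(np.exp(np.sum(np.log(ks)) - np.sum(np.log(lams))))


def sample_delay(delay: DelayDistribution, rng: np.random.Generator, size=None):
    """Draw from a delay law (thin wrapper around :meth:`DelayDistribution.sample`)."""
    return delay.sample(rng, size=size)
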