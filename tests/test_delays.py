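"""Delay-distribution algebra: closed forms vs independent oracles."""

import numpy as np
import pytest
from scipy import stats

from dcme import (DelayDistribution, GridError, ParameterError, arrival_probability,
                  compound_cdf_T, convolve_pdfs, erlang_cdf, erlang_pdf, hypoexp_cdf,
                  hypoexp_pdf, sample_delay)

K = 0.2


def _trapz_convolve(f, g, dt):
    """Independent trapezoid-rule convolution oracle (plain numpy)."""
    out = np.convolve(f, g)[: f.size]
    return (out - 0.5 * (f[0] * g + g[0] * f)) * dt


class TestErlangClosedForms:
    def test_pdf_support_and_origin(self):
        assert erlang_pdf(0.0, 3, K) == 0.0
        assert erlang_pdf(-1.0, 3, K) == 0.0
        assert erlang_pdf(0.0, 1, 2.0) == 2.0  # exponential density at 0

    def test_pdf_matches_triple_convolution_oracle(self):
        # tau_41 = tau_21 * tau_32 * tau_43: convolve three Exp(k) densities
        # numerically (independent of the package's convolution helper)
        dt = 0.002
        grid = np.arange(0, 60, dt)
        expo = K * np.exp(-K * grid)
        conv = _trapz_convolve(_trapz_convolve(expo, expo, dt), expo, dt)
        i5 = int(round(5.0 / dt))
        assert conv[i5] == pytest.approx(erlang_pdf(5.0, 3, K), abs=1e-6)

    def test_cdf_limits(self):
        assert erlang_cdf(0.0, 3, K) == 0.0
        assert erlang_cdf(-2.0, 5, 1.0) == 0.0
        assert erlang_cdf(1e4, 3, K) == pytest.approx(1.0, abs=1e-12)

    def test_cdf_chain_identity(self):
        # T40(t) = T41(t) - tau_40(t)/k for the equal-rate four-step chain
        t = np.linspace(0.0, 50.0, 301)
        T40 = erlang_cdf(t, 4, K)
        T41 = erlang_cdf(t, 3, K)
        tau40 = erlang_pdf(t, 4, K)
        np.testing.assert_allclose(T40, T41 - tau40 / K, atol=1e-14)

    def test_cdf_is_antiderivative_of_pdf(self):
        t = np.linspace(0.01, 40, 400)
        dcdf = np.gradient(erlang_cdf(t, 3, K), t)
        np.testing.assert_allclose(dcdf, erlang_pdf(t, 3, K), atol=2e-4)

    @pytest.mark.parametrize("r,beta", [(0, 1.0), (3, 0.0), (2.5, 1.0)])
    def test_parameter_validation(self, r, beta):
        with pytest.raises(ParameterError):
            erlang_pdf(1.0, r, beta)


class TestHypoexponential:
    def test_pdf_matches_numeric_convolution(self):
        rates = [1.0, 2.0, 3.5]
        dt = 0.001
        grid = np.arange(0, 25, dt)
        conv = rates[0] * np.exp(-rates[0] * grid)
        for lam in rates[1:]:
            conv = _trapz_convolve(conv, lam * np.exp(-lam * grid), dt)
        for t in (0.5, 1.0, 3.0):
            assert hypoexp_pdf(t, rates) == pytest.approx(conv[int(round(t / dt))], abs=1e-5)

    def test_cdf_pdf_consistency(self):
        rates = [0.7, 1.3, 2.1]
        t = np.linspace(0.2, 15, 3000)
        dcdf = np.gradient(hypoexp_cdf(t, rates), t)
        np.testing.assert_allclose(dcdf[1:-1], hypoexp_pdf(t, rates)[1:-1], atol=1e-4)

    def test_repeated_rates_rejected_in_closed_form(self):
        with pytest.raises(ParameterError):
            hypoexp_pdf(1.0, [2.0, 2.0])

    def test_family_routes_repeated_rates_to_erlang(self):
        d = DelayDistribution.hypoexponential([2.0, 2.0, 2.0])
        t = np.linspace(0, 5, 50)
        np.testing.assert_allclose(d.pdf(t), erlang_pdf(t, 3, 2.0), atol=1e-12)

    def test_mixed_multiplicity_routes_to_numeric(self):
        d = DelayDistribution.hypoexponential([1.0, 1.0, 3.0])
        # oracle: convolve Erlang(2,1) with Exp(3) numerically
        dt = 0.002
        grid = np.arange(0, 40, dt)
        conv = _trapz_convolve(erlang_pdf(grid, 2, 1.0), 3.0 * np.exp(-3.0 * grid), dt)
        for t in (0.5, 2.0, 5.0):
            assert d.pdf(t) == pytest.approx(conv[int(round(t / dt))], abs=2e-3)


class TestCompoundCdf:
    def test_zero_delay_reduces_to_exponential(self):
        t = np.linspace(0, 20, 41)
        T = compound_cdf_T(t, K, DelayDistribution.zero())
        np.testing.assert_allclose(T, 1.0 - np.exp(-K * t), atol=1e-14)

    def test_constant_delay_shifted_exponential(self):
        s = 5.0
        d = DelayDistribution.constant(s)
        assert compound_cdf_T(3.0, K, d) == 0.0
        assert compound_cdf_T(12.0, K, d) == pytest.approx(1 - np.exp(-K * 7.0), abs=1e-14)

    def test_equal_rate_erlang_gives_next_erlang(self):
        d = DelayDistribution.erlang(3, K)
        t = np.linspace(0, 40, 81)
        np.testing.assert_allclose(compound_cdf_T(t, K, d), erlang_cdf(t, 4, K), atol=1e-14)

    def test_monte_carlo_oracle(self):
        # CDF of Exp(k) + Erlang(3, k) from 1e6 direct draws
        rng = np.random.default_rng(7)
        draws = rng.exponential(1 / K, 10**6) + rng.gamma(3, 1 / K, 10**6)
        d = DelayDistribution.erlang(3, K)
        for t in (5.0, 12.0, 25.0):
            mc = float(np.mean(draws <= t))
            se = np.sqrt(mc * (1 - mc) / 10**6)
            assert compound_cdf_T(t, K, d) == pytest.approx(mc, abs=4 * se)

    def test_numeric_path_matches_closed_form(self):
        # erlang with rate != k exercises the quadrature branch; oracle is the
        # distinct-rate hypoexponential formula on (k, beta) with r=1 extended
        # by Monte Carlo for r=2
        rng = np.random.default_rng(11)
        k, beta, r = 0.5, 1.7, 2
        draws = rng.exponential(1 / k, 10**6) + rng.gamma(r, 1 / beta, 10**6)
        d = DelayDistribution.erlang(r, beta)
        for t in (1.0, 4.0, 8.0):
            mc = float(np.mean(draws <= t))
            se = np.sqrt(mc * (1 - mc) / 10**6)
            assert compound_cdf_T(t, k, d) == pytest.approx(mc, abs=4 * se)

    @pytest.mark.parametrize(
        "delay",
        [DelayDistribution.zero(), DelayDistribution.constant(4.0),
         DelayDistribution.erlang(3, K), DelayDistribution.hypoexponential([0.3, 0.9])],
        ids=["zero", "constant", "erlang", "hypoexp"],
    )
    def test_cdf_properties(self, delay):
        # non-decreasing with limits 0 and 1
        t = np.linspace(0, 200, 400)
        T = np.atleast_1d(compound_cdf_T(t, K, delay))
        assert T[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(T) >= -1e-12)
        assert T[-1] == pytest.approx(1.0, abs=1e-8)


class TestArrivalProbability:
    def test_no_degradation_certain_arrival(self):
        assert arrival_probability([1.0] * 5, [1.0] * 5) == pytest.approx(1.0)

    def test_single_step_competing_exponentials(self):
        assert arrival_probability([1.0], [1.2]) == pytest.approx(1 / 1.2)

    def test_seven_step_chain_vs_monte_carlo(self):
        # simulate exponential races through the chain: a walker survives a
        # step iff the forward Exp(k) beats the degradation Exp(mu)
        rng = np.random.default_rng(3)
        n, r, k, mu = 200_000, 7, 1.0, 0.2
        fwd = rng.exponential(1 / k, (n, r))
        die = rng.exponential(1 / mu, (n, r))
        frac = float(np.mean(np.all(fwd < die, axis=1)))
        p = arrival_probability([k] * r, [k + mu] * r)
        assert p == pytest.approx((1 / 1.2) ** 7, rel=1e-12)
        assert p == pytest.approx(frac, abs=4 * np.sqrt(frac * (1 - frac) / n))

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            arrival_probability([1.0, 1.0], [1.2])


class TestConvolution:
    def test_single_pdf_identity(self):
        grid = np.linspace(0, 10, 500)
        pdf = erlang_pdf(grid, 2, 1.0)
        np.testing.assert_array_equal(convolve_pdfs([pdf], grid), pdf)

    def test_three_exponentials_give_erlang(self):
        grid = np.arange(0, 80, 0.002)
        expo = K * np.exp(-K * grid)
        conv = convolve_pdfs([expo, expo, expo], grid)
        assert np.max(np.abs(conv - erlang_pdf(grid, 3, K))) < 1e-6

    def test_narrow_pulse_sifts(self):
        grid = np.arange(0, 40, 0.001)
        width = 0.003
        pulse = np.where(grid < width, 1.0 / width, 0.0)
        pulse /= 0.001 * (pulse.sum() - 0.5 * pulse[0])  # unit trapezoid mass
        expo = np.exp(-grid)
        conv = convolve_pdfs([pulse, expo], grid)
        idx = grid > 0.1
        assert np.max(np.abs(conv[idx] - np.exp(-(grid[idx] - width / 2)))) < 5e-3

    def test_non_uniform_grid_rejected(self):
        grid = np.array([0.0, 1.0, 3.0, 4.0])
        with pytest.raises(GridError):
            convolve_pdfs([np.ones(4)], grid)


class TestSampling:
    def test_degenerate_families(self):
        rng = np.random.default_rng(0)
        assert sample_delay(DelayDistribution.zero(), rng) == 0.0
        assert sample_delay(DelayDistribution.constant(3.5), rng) == 3.5

    def test_erlang_sample_mean(self):
        rng = np.random.default_rng(5)
        draws = sample_delay(DelayDistribution.erlang(3, K), rng, size=10**5)
        se = np.sqrt(3 / K**2 / 10**5)
        assert draws.mean() == pytest.approx(3 / K, abs=3 * se)

    @pytest.mark.parametrize(
        "delay",
        [DelayDistribution.erlang(3, K),
         DelayDistribution.hypoexponential([0.5, 1.1, 2.3]),
         DelayDistribution.hypoexponential([1.0, 1.0, 4.0])],
        ids=["erlang", "hypoexp-distinct", "hypoexp-mixed"],
    )
    def test_kolmogorov_smirnov_agreement(self, delay):
        rng = np.random.default_rng(13)
        draws = delay.sample(rng, size=10**4)
        stat = stats.kstest(draws, lambda x: np.atleast_1d(delay.cdf(x)))
        assert stat.pvalue > 0.01

    def test_tabulated_round_trips_erlang(self):
        grid = np.linspace(0, 120, 4096)
        tab = DelayDistribution.tabulated(grid, erlang_pdf(grid, 3, K))
        rng = np.random.default_rng(17)
        draws = tab.sample(rng, size=10**4)
        stat = stats.kstest(draws, lambda x: erlang_cdf(x, 3, K))
        assert stat.pvalue > 0.01
        assert tab.mean() == pytest.approx(15.0, rel=1e-3)
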