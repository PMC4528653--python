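"""Simulation engines: exactness against closed forms and cross-engine equivalence."""

import numpy as np
import pytest
from scipy import stats

from dcme import (DelayDistribution, Modulator, PendingEvent, QueryError, Reaction,
                  ReactionSystem, UsageError, build_five_state_chain, compare_distributions,
                  distribution_from_states, ensemble_distribution, erlang_cdf,
                  marginal_counts, run_ensemble, simulate_direct, simulate_rejection,
                  simulate_ssa, simulate_time_varying)

K, N = 0.2, 100


def _decay_system(n=100, k=0.2):
    return ReactionSystem(["A"], [Reaction("deg", {"A": 1}, {}, k)], [n])


class TestPlainSSA:
    def test_unimolecular_decay_mean(self):
        st_arr = run_ensemble(_decay_system(), 3000, [5.0], 101, engine="ssa")
        mean = st_arr[:, 0, 0].mean()
        expected = 100 * np.exp(-0.2 * 5.0)
        se = np.sqrt(100 * np.exp(-1.0) * (1 - np.exp(-1.0)) / 3000)
        assert abs(mean - expected) < 3 * se

    def test_full_chain_terminal_mean_is_first_passage_cdf(self, five_state_full):
        st_arr = run_ensemble(five_state_full, 3000, [12.0], 103, engine="ssa")
        mean_s4 = st_arr[:, 0, 4].mean()
        p = erlang_cdf(12.0, 4, K)
        se = np.sqrt(N * p * (1 - p) / 3000)
        assert abs(mean_s4 - N * p) < 3 * se

    def test_rejects_delayed_systems(self, five_state_abridged):
        with pytest.raises(UsageError):
            simulate_ssa(five_state_abridged, 1.0, seed=0)

    def test_zero_propensity_constant_trajectory(self):
        sys = ReactionSystem(["A"], [Reaction("r", {"A": 1}, {}, 1.0)], [0])
        tr = simulate_ssa(sys, 10.0, seed=0)
        assert tr.n_events == 0
        np.testing.assert_array_equal(tr.state_at(10.0), [0])


class TestRejectionEngine:
    def test_source_mean_follows_exponential_decay(self, five_state_abridged):
        st_arr = run_ensemble(five_state_abridged, 3000, [6.0, 12.0], 107)
        for j, t in enumerate((6.0, 12.0)):
            p = np.exp(-K * t)
            se = np.sqrt(N * p * (1 - p) / 3000)
            assert abs(st_arr[:, j, 0].mean() - N * p) < 3 * se

    def test_single_walker_inflight_state_is_empty(self):
        sys = build_five_state_chain(K, 1, abridged=True)
        tr = simulate_rejection(sys, 200.0, seed=5)
        kinds = tr.kinds
        assert kinds[0] == "initiate"
        np.testing.assert_array_equal(tr.states[0], (0, 0))
        assert kinds[1] == "complete"
        np.testing.assert_array_equal(tr.states[1], (0, 1))

    def test_walker_conservation_with_inflight(self, five_state_abridged):
        tr = simulate_rejection(five_state_abridged, 12.0, seed=9)
        inflight = 0
        for kind, state in zip(tr.kinds, tr.states):
            inflight += {"initiate": 1, "complete": -1}.get(kind, 0)
            assert state[0] + state[1] + inflight == N
            assert min(state) >= 0
        assert inflight == tr.pending_at_end

    def test_initial_history_completes_at_due_time(self):
        base = build_five_state_chain(K, 1, abridged=True)
        sys = ReactionSystem(base.species, base.reactions, [0, 0],
                             initial_history=[PendingEvent("R40", 3.0)])
        tr = simulate_rejection(sys, 10.0, seed=1)
        assert tr.kinds == ["complete"]
        assert tr.times == [3.0]
        np.testing.assert_array_equal(tr.state_at(2.9), [0, 0])
        np.testing.assert_array_equal(tr.state_at(3.0), [0, 1])

    def test_seed_reproducibility(self, five_state_abridged):
        a = simulate_rejection(five_state_abridged, 12.0, seed=42)
        b = simulate_rejection(five_state_abridged, 12.0, seed=42)
        assert a.times == b.times and a.states == b.states
        c = run_ensemble(five_state_abridged, 50, [12.0], 42)
        d = run_ensemble(five_state_abridged, 50, [12.0], 42)
        np.testing.assert_array_equal(c, d)


class TestDirectEngine:
    def test_matches_rejection_distribution(self, five_state_abridged):
        n_runs = 4000
        a = run_ensemble(five_state_abridged, n_runs, [12.0], 201, engine="rejection")
        b = run_ensemble(five_state_abridged, n_runs, [12.0], 202, engine="direct")
        rep = compare_distributions(
            distribution_from_states(a[:, 0, :]), distribution_from_states(b[:, 0, :]),
            n_p=n_runs, n_q=n_runs)
        assert stats.chi2.sf(rep.chi_square, rep.dof) > 0.01

    def test_matches_rejection_on_mrna_model(self, mrna_abridged):
        n_runs = 3000
        a = run_ensemble(mrna_abridged, n_runs, [12.0], 203, engine="rejection")
        b = run_ensemble(mrna_abridged, n_runs, [12.0], 204, engine="direct")
        rep = compare_distributions(
            distribution_from_states(a[:, 0, :]), distribution_from_states(b[:, 0, :]),
            n_p=n_runs, n_q=n_runs)
        assert stats.chi2.sf(rep.chi_square, rep.dof) > 0.01

    def test_empty_queue_reduces_to_ssa_distribution(self):
        n_runs = 3000
        a = run_ensemble(_decay_system(30, 0.5), n_runs, [2.0], 205, engine="direct")
        b = run_ensemble(_decay_system(30, 0.5), n_runs, [2.0], 206, engine="ssa")
        rep = compare_distributions(
            distribution_from_states(a[:, 0, :]), distribution_from_states(b[:, 0, :]),
            n_p=n_runs, n_q=n_runs)
        assert stats.chi2.sf(rep.chi_square, rep.dof) > 0.01

    def test_walker_conservation(self, five_state_abridged):
        tr = simulate_direct(five_state_abridged, 12.0, seed=11)
        inflight = 0
        for kind, state in zip(tr.kinds, tr.states):
            inflight += {"initiate": 1, "complete": -1}.get(kind, 0)
            assert state[0] + state[1] + inflight == N


class TestZeroDelayEquivalence:
    """With all delays set to the zero law, the delay engines must reproduce
    the plain SSA distribution of the equivalent instantaneous model."""

    @pytest.mark.parametrize("engine", ["rejection", "direct"])
    @pytest.mark.parametrize("delay_class", ["consuming", "nonconsuming"])
    def test_zero_delay_matches_ssa(self, engine, delay_class):
        zero = DelayDistribution.zero()
        delayed = ReactionSystem(
            ["A", "B"],
            [Reaction("r", {"A": 1}, {"B": 1}, 1.0, delay_class=delay_class, delay=zero)],
            [30, 0])
        plain = ReactionSystem(
            ["A", "B"], [Reaction("r", {"A": 1}, {"B": 1}, 1.0)], [30, 0])
        n_runs = 2500
        a = run_ensemble(delayed, n_runs, [1.0], 301, engine=engine)
        b = run_ensemble(plain, n_runs, [1.0], 302, engine="ssa")
        rep = compare_distributions(
            distribution_from_states(a[:, 0, :]), distribution_from_states(b[:, 0, :]),
            n_p=n_runs, n_q=n_runs)
        assert stats.chi2.sf(rep.chi_square, rep.dof) > 0.01


class _UnitModulator(Modulator):
    def value(self, t):
        return 1.0

    def integral(self, t0, t1):
        return t1 - t0


class _RampModulator(Modulator):
    """g(t) = t / 10 with its closed-form antiderivative."""

    def value(self, t):
        return t / 10.0

    def integral(self, t0, t1):
        return (t1**2 - t0**2) / 20.0


class TestTimeVarying:
    def test_unit_modulator_matches_ssa(self):
        sys = _decay_system(30, 0.5)
        n_runs = 2000
        a = run_ensemble(sys, n_runs, [2.0], 401, engine="tv",
                         rate_modulators={"deg": _UnitModulator()})
        b = run_ensemble(sys, n_runs, [2.0], 402, engine="ssa")
        rep = compare_distributions(
            distribution_from_states(a[:, 0, :]), distribution_from_states(b[:, 0, :]),
            n_p=n_runs, n_q=n_runs)
        assert stats.chi2.sf(rep.chi_square, rep.dof) > 0.01

    def test_zero_modulator_silences_reaction(self):
        sys = _decay_system(30, 0.5)
        tr = simulate_time_varying(sys, {"deg": lambda t: 0.0}, 5.0, seed=1)
        assert tr.n_events == 0
        np.testing.assert_array_equal(tr.state_at(5.0), [30])

    def test_rejects_delayed_systems(self, five_state_abridged):
        with pytest.raises(UsageError):
            simulate_time_varying(five_state_abridged, {}, 1.0, seed=0)

    def test_ramp_modulator_matches_time_transformed_poisson(self):
        # pure birth with g(t) = t/10 on [0,10]: count at t is Poisson with
        # mean k * t^2/20 — an independent closed-form oracle
        sys = ReactionSystem(["X"], [Reaction("b", {}, {"X": 1}, 2.0)], [0])
        n_runs = 2000
        st_arr = run_ensemble(sys, n_runs, [10.0], 403, engine="tv",
                              rate_modulators={"b": _RampModulator()})
        lam = 2.0 * 10.0**2 / 20.0
        mean = st_arr[:, 0, 0].mean()
        assert abs(mean - lam) < 3 * np.sqrt(lam / n_runs)
        pmf = marginal_counts(st_arr[:, 0, :], 0)
        ref = stats.poisson.pmf(np.arange(pmf.size), lam)
        assert np.max(np.abs(pmf - ref)) < 4 * np.sqrt(ref.max() / n_runs) + 1.0 / n_runs


class TestEnsembleUtilities:
    def test_single_trajectory_point_mass(self, five_state_abridged):
        tr = simulate_rejection(five_state_abridged, 12.0, seed=3)
        dist = ensemble_distribution([tr], 12.0)
        assert len(dist) == 1
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, five_state_abridged):
        trs = [simulate_rejection(five_state_abridged, 12.0, seed=s) for s in range(20)]
        dist = ensemble_distribution(trs, 12.0)
        assert sum(dist.values()) == pytest.approx(1.0)
        sub = ensemble_distribution(trs, 12.0, species_subset=[1])
        assert sum(sub.values()) == pytest.approx(1.0)
        assert all(len(k) == 1 for k in sub)

    def test_query_outside_horizon(self, five_state_abridged):
        tr = simulate_rejection(five_state_abridged, 12.0, seed=3)
        with pytest.raises(QueryError):
            tr.state_at(12.5)

    def test_snapshot_readoff_applies_due_completions(self):
        base = build_five_state_chain(K, 1, abridged=True)
        sys = ReactionSystem(base.species, base.reactions, [0, 0],
                             initial_history=[PendingEvent("R40", 3.0)])
        tr = simulate_rejection(sys, 5.0, seed=1, snapshot_times=[2.0, 3.0, 4.0])
        np.testing.assert_array_equal(tr.snapshots, [[0, 0], [0, 1], [0, 1]])
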