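"""Exact stochastic simulation of delayed reaction systems.

Four engines, all statistically exact for their model class:

``simulate_rejection``
    delay SSA that draws a tentative next-reaction time and *rejects* it
    whenever a pending delayed update falls inside the waiting interval; the
    pending update is applied, propensities are refreshed and the waiting
    time redrawn.
``simulate_direct``
    delay SSA that never rejects: it accumulates the exponential hazard
    piecewise across the intervals between pending update times (the
    propensities are constant on each interval) and inverts it for the next
    firing time.
``simulate_ssa``
    plain Gillespie direct method for delay-free systems.
``simulate_time_varying``
    SSA for propensities of the form ``a_j(X) * g_j(t)`` with bounded
    deterministic modulators ``g_j``; next-event times come from integrated-
    hazard inversion.

Delayed-reaction semantics follow the consuming / non-consuming
classification: a non-consuming reaction applies its whole update at delay
completion, a consuming reaction removes reactants at initiation and adds
products at completion.  Reproducibility: each run in an ensemble uses the
child ``i`` of ``numpy.random.SeedSequence(base_seed)``.
"""

from __future__ import annotations

import heapq
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import count
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import integrate, optimize, special

from .errors import ParameterError, QueryError, StateUnderflowError, UsageError
from .model import ReactionSystem

__all__ = [
    "Trajectory",
    "simulate_rejection",
    "simulate_direct",
    "simulate_ssa",
    "simulate_time_varying",
    "run_ensemble",
    "ensemble_distribution",
    "distribution_from_states",
    "marginal_counts",
    "Modulator",
    "CdfModulator",
    "ErlangCdfModulator",
]

_FIRE, _INITIATE, _COMPLETE = "fire", "initiate", "complete"


@dataclass
class Trajectory:
    """Event log of one simulation run.

    ``times``/``kinds``/``reaction_ids``/``states`` are parallel lists, one
    entry per state-changing or scheduling event (``fire``, ``initiate``,
    ``complete``); ``states`` holds the state *after* the event.  The state
    read-off convention applies events due exactly at the query time before
    reading.
    """

    species: list[str]
    t0: float
    x0: tuple
    t_end: float
    seed: object = None
    times: list = field(default_factory=list)
    kinds: list = field(default_factory=list)
    reaction_ids: list = field(default_factory=list)
    states: list = field(default_factory=list)
    snapshot_times: np.ndarray | None = None
    snapshots: np.ndarray | None = None
    pending_at_end: int = 0

    def state_at(self, t: float) -> np.ndarray:
        if t < self.t0 or t > self.t_end:
            raise QueryError(f"time {t} outside simulated horizon [{self.t0}, {self.t_end}]")
        i = bisect_right(self.times, t)
        return np.asarray(self.x0 if i == 0 else self.states[i - 1], dtype=np.int64)

    @property
    def n_events(self) -> int:
        return len(self.times)


class _Compiled:
    """Flattened per-reaction tuples for fast inner loops."""

    __slots__ = ("n_species", "rxns", "ids")

    def __init__(self, system: ReactionSystem):
        self.n_species = len(system.species)
        self.rxns = []
        self.ids = []
        for r in system.reactions:
            code = {"none": 0, "nonconsuming": 1, "consuming": 2}[r.delay_class]
            if code == 0:
                init_upd = _sparse(r.nu)
                comp_upd = None
            elif code == 1:
                init_upd = ()
                comp_upd = _sparse(r.nu)
            else:
                init_upd = _sparse(r.nu_r)
                comp_upd = _sparse(r.nu_p)
            self.rxns.append(
                (r.rate_constant, r.reactant_pairs, code, init_upd, comp_upd, r.delay, r.id)
            )
            self.ids.append(r.id)


def _sparse(vec: np.ndarray) -> tuple:
    return tuple((i, int(d)) for i, d in enumerate(vec) if d)


def _propensities(rxns, state) -> list:
    out = []
    for rate, pairs, *_ in rxns:
        a = rate
        for i, c in pairs:
            x = state[i]
            if c == 1:
                a *= x
            else:
                for m in range(c):
                    a *= x - m
            if a <= 0.0:
                a = 0.0
                break
        out.append(a)
    return out


def _apply(state: list, upd) -> None:
    for i, d in upd:
        state[i] += d
        if state[i] < 0:
            raise StateUnderflowError(f"species index {i} went negative")


def _init_pending(system: ReactionSystem, seq) -> list:
    heap = []
    for ev in system.initial_history:
        heapq.heappush(
            heap, (ev.due_time, next(seq), _sparse(ev.completion_update), ev.reaction_id)
        )
    return heap


class _Recorder:
    """Collects the event log and flushes snapshot grid points.

    ``flush(upto)`` records every snapshot time strictly before ``upto`` with
    the current state; it is called immediately before each event is applied,
    so a snapshot exactly at an event time sees the post-event state.
    """

    __slots__ = ("traj", "record", "snap_times", "snap_out", "snap_i", "state")

    def __init__(self, traj: Trajectory, record: bool, snapshot_times, state: list):
        self.traj = traj
        self.record = record
        self.state = state
        if snapshot_times is not None:
            self.snap_times = np.asarray(snapshot_times, dtype=float)
            self.snap_out = np.empty((self.snap_times.size, len(state)), dtype=np.int64)
        else:
            self.snap_times = None
            self.snap_out = None
        self.snap_i = 0

    def flush(self, upto: float) -> None:
        st = self.snap_times
        if st is None:
            return
        while self.snap_i < st.size and st[self.snap_i] < upto:
            self.snap_out[self.snap_i] = self.state
            self.snap_i += 1

    def finish(self, t_end: float) -> None:
        st = self.snap_times
        if st is not None:
            while self.snap_i < st.size and st[self.snap_i] <= t_end:
                self.snap_out[self.snap_i] = self.state
                self.snap_i += 1
            if self.snap_i < st.size:
                raise QueryError("snapshot time beyond simulation horizon")
            self.traj.snapshot_times = st
            self.traj.snapshots = self.snap_out

    def event(self, t: float, kind: str, rid: str) -> None:
        if self.record:
            tr = self.traj
            tr.times.append(t)
            tr.kinds.append(kind)
            tr.reaction_ids.append(rid)
            tr.states.append(tuple(self.state))


def _make_traj(system, t_end, seed, record_note=None) -> Trajectory:
    return Trajectory(
        species=list(system.species),
        t0=system.time_origin,
        x0=tuple(int(x) for x in system.initial_state),
        t_end=float(t_end),
        seed=seed,
    )


def _resolve_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# rejection method
# --------------------------------------------------------------------------

def simulate_rejection(
    system: ReactionSystem,
    t_end: float,
    seed=None,
    snapshot_times: Sequence[float] | None = None,
    record_events: bool = True,
) -> Trajectory:
    """Exact delay-SSA sample via the rejection method."""
    if t_end <= system.time_origin:
        raise ParameterError("t_end must exceed the system time origin")
    rng = _resolve_rng(seed)
    comp = _Compiled(system)
    return _run_rejection(system, comp, t_end, rng, seed, snapshot_times, record_events)


def _run_rejection(system, comp, t_end, rng, seed, snapshot_times, record_events):
    rxns = comp.rxns
    n_rxn = len(rxns)
    state = [int(x) for x in system.initial_state]
    t = system.time_origin
    seq = count()
    pending = _init_pending(system, seq)
    traj = _make_traj(system, t_end, seed)
    rec = _Recorder(traj, record_events, snapshot_times, state)
    rand = rng.random
    log = math.log
    props = _propensities(rxns, state)
    a0 = sum(props)
    while True:
        if a0 <= 0.0:
            if pending and pending[0][0] <= t_end:
                due, _, upd, rid = heapq.heappop(pending)
                rec.flush(due)
                t = due
                _apply(state, upd)
                rec.event(t, _COMPLETE, rid)
                props = _propensities(rxns, state)
                a0 = sum(props)
                continue
            break
        t_next = t + -log(1.0 - rand()) / a0
        limit = t_end if t_next > t_end else t_next
        if pending and pending[0][0] <= limit:
            # a pending completion pre-empts the tentative firing: reject & redraw
            due, _, upd, rid = heapq.heappop(pending)
            rec.flush(due)
            t = due
            _apply(state, upd)
            rec.event(t, _COMPLETE, rid)
            props = _propensities(rxns, state)
            a0 = sum(props)
            continue
        if t_next > t_end:
            break
        rec.flush(t_next)
        t = t_next
        if n_rxn == 1:
            j = 0
        else:
            v = rand() * a0
            acc = 0.0
            for j in range(n_rxn):
                acc += props[j]
                if v < acc:
                    break
        rate, pairs, code, init_upd, comp_upd, delay, rid = rxns[j]
        if code == 0:
            _apply(state, init_upd)
            rec.event(t, _FIRE, rid)
        else:
            d = delay.sample(rng)
            heapq.heappush(pending, (t + d, next(seq), comp_upd, rid))
            if code == 2:
                _apply(state, init_upd)
            rec.event(t, _INITIATE, rid)
        props = _propensities(rxns, state)
        a0 = sum(props)
    rec.finish(t_end)
    traj.pending_at_end = len(pending)
    return traj


# --------------------------------------------------------------------------
# direct (piecewise-hazard) method
# --------------------------------------------------------------------------

def simulate_direct(
    system: ReactionSystem,
    t_end: float,
    seed=None,
    snapshot_times: Sequence[float] | None = None,
    record_events: bool = True,
) -> Trajectory:
    """Exact delay-SSA sample via the direct (piecewise-PDF) method.

    With pending update times ``T_1 < ... < T_k`` the propensities are
    constant on each interval, so the next-reaction hazard is piecewise
    linear: the interval index ``i`` satisfying

        sum_{j<=i} (T_j - T_{j-1}) a0(X(T_{j-1}))  <=  ln(1/r)  <  sum_{j<=i+1} ...

    locates the firing interval; completions due at ``T_1..T_i`` are applied
    in order and the firing time is ``T_i`` plus the residual hazard divided
    by ``a0(X(T_i))``.
    """
    if t_end <= system.time_origin:
        raise ParameterError("t_end must exceed the system time origin")
    rng = _resolve_rng(seed)
    comp = _Compiled(system)
    rxns = comp.rxns
    n_rxn = len(rxns)
    state = [int(x) for x in system.initial_state]
    t = system.time_origin
    seq = count()
    pending = _init_pending(system, seq)
    traj = _make_traj(system, t_end, seed)
    rec = _Recorder(traj, record_events, snapshot_times, state)
    rand = rng.random
    log = math.log
    props = _propensities(rxns, state)
    a0 = sum(props)
    done = False
    while not done:
        target = -log(1.0 - rand())  # ln(1/r)
        acc = 0.0
        cur = t
        while True:
            nxt = pending[0][0] if pending else math.inf
            seg_end = nxt if nxt < t_end else t_end
            if a0 > 0.0 and seg_end > cur:
                seg = (seg_end - cur) * a0
                if acc + seg >= target:
                    t_fire = cur + (target - acc) / a0
                    rec.flush(t_fire)
                    t = t_fire
                    if n_rxn == 1:
                        j = 0
                    else:
                        v = rand() * a0
                        run = 0.0
                        for j in range(n_rxn):
                            run += props[j]
                            if v < run:
                                break
                    rate, pairs, code, init_upd, comp_upd, delay, rid = rxns[j]
                    if code == 0:
                        _apply(state, init_upd)
                        rec.event(t, _FIRE, rid)
                    else:
                        d = delay.sample(rng)
                        heapq.heappush(pending, (t + d, next(seq), comp_upd, rid))
                        if code == 2:
                            _apply(state, init_upd)
                        rec.event(t, _INITIATE, rid)
                    props = _propensities(rxns, state)
                    a0 = sum(props)
                    break
                acc += seg
            if nxt <= t_end:
                due, _, upd, rid = heapq.heappop(pending)
                rec.flush(due)
                cur = due
                t = due
                _apply(state, upd)
                rec.event(t, _COMPLETE, rid)
                props = _propensities(rxns, state)
                a0 = sum(props)
                continue
            # hazard to t_end exhausted and no applicable completions remain
            t = t_end
            done = True
            break
    rec.finish(t_end)
    traj.pending_at_end = len(pending)
    return traj


# --------------------------------------------------------------------------
# plain SSA
# --------------------------------------------------------------------------

def simulate_ssa(
    system: ReactionSystem,
    t_end: float,
    seed=None,
    snapshot_times: Sequence[float] | None = None,
    record_events: bool = True,
) -> Trajectory:
    """Gillespie direct-method sample for a delay-free system."""
    if system.has_delays:
        raise UsageError("simulate_ssa requires a delay-free system; use a delay SSA")
    # with no delayed reactions the rejection engine *is* the direct method
    return simulate_rejection(system, t_end, seed, snapshot_times, record_events)


# --------------------------------------------------------------------------
# time-varying propensities
# --------------------------------------------------------------------------

class Modulator:
    """A deterministic time factor ``g(t)`` multiplying a reaction propensity.

    Subclasses may override :meth:`integral` with a closed form; the default
    integrates numerically.  ``bound`` must dominate ``g`` on the horizon.
    """

    bound = 1.0

    def value(self, t: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def integral(self, t0: float, t1: float) -> float:
        val, _ = integrate.quad(self.value, t0, t1, epsabs=1e-12, epsrel=1e-10, limit=200)
        return val


class CdfModulator(Modulator):
    """Modulator equal to the CDF of a delay law (bounded by 1)."""

    def __init__(self, delay):
        self.delay = delay

    def value(self, t: float) -> float:
        return float(self.delay.cdf(t))


class ErlangCdfModulator(Modulator):
    """Erlang(r, beta) CDF with a closed-form time integral.

    ``int_0^t F(s) ds = t - (1/beta) * sum_{j=1}^{r} P(j, beta t)`` where
    ``P`` is the regularized lower incomplete gamma function (the Erlang(j)
    CDF), obtained by integrating the survival series term by term.
    """

    def __init__(self, shape: int, rate: float):
        if int(shape) != shape or shape < 1 or rate <= 0:
            raise ParameterError("ErlangCdfModulator needs integer shape >= 1 and rate > 0")
        self.shape = int(shape)
        self.rate = float(rate)
        self._js = np.arange(1, self.shape + 1)

    def value(self, t: float) -> float:
        if t <= 0:
            return 0.0
        return float(special.gammainc(self.shape, self.rate * t))

    def _antideriv(self, t: float) -> float:
        if t <= 0:
            return 0.0
        return t - float(np.sum(special.gammainc(self._js, self.rate * t))) / self.rate

    def integral(self, t0: float, t1: float) -> float:
        return self._antideriv(t1) - self._antideriv(t0)


def simulate_time_varying(
    system: ReactionSystem,
    rate_modulators: Mapping[str, Modulator | Callable[[float], float]],
    t_end: float,
    seed=None,
    snapshot_times: Sequence[float] | None = None,
    record_events: bool = True,
) -> Trajectory:
    """Exact SSA for propensities ``a_j(X) * g_j(t)``.

    Firing times solve the integrated-hazard equation
    ``int_t^{t+D} sum_j a_j(X) g_j(s) ds = ln(1/u)`` by bracketed root
    finding on ``[0, t_end - t]`` (the hazard integral is monotone in ``D``);
    the firing reaction is selected proportionally to ``a_j(X) g_j(t*)`` at
    the firing time.  Plain callables are wrapped in :class:`Modulator` with
    numerical integration.
    """
    if system.has_delays:
        raise UsageError("simulate_time_varying expects a delay-free system")
    if t_end <= system.time_origin:
        raise ParameterError("t_end must exceed the system time origin")
    rng = _resolve_rng(seed)
    comp = _Compiled(system)
    rxns = comp.rxns
    n_rxn = len(rxns)
    mods: list[Modulator | None] = [None] * n_rxn
    known = set(comp.ids)
    for rid, g in rate_modulators.items():
        if rid not in known:
            raise ParameterError(f"modulator references unknown reaction {rid}")
        if not isinstance(g, Modulator):
            g = _CallableModulator(g)
        mods[comp.ids.index(rid)] = g

    state = [int(x) for x in system.initial_state]
    t = system.time_origin
    traj = _make_traj(system, t_end, seed)
    rec = _Recorder(traj, record_events, snapshot_times, state)
    rand = rng.random
    log = math.log

    while t < t_end:
        props = _propensities(rxns, state)
        const_rate = sum(a for a, g in zip(props, mods) if g is None)
        active = [(a, g) for a, g in zip(props, mods) if g is not None and a > 0.0]
        target = -log(1.0 - rand())

        def hazard(dd: float) -> float:
            h = const_rate * dd
            for a, g in active:
                h += a * g.integral(t, t + dd)
            return h

        horizon = t_end - t
        if hazard(horizon) < target:
            break  # no further firing before t_end
        if not active:
            dd = target / const_rate
        else:
            dd = optimize.brentq(
                lambda x: hazard(x) - target, 0.0, horizon, xtol=1e-12, rtol=1e-12
            )
        t_fire = t + dd
        weights = [
            a * (g.value(t_fire) if g is not None else 1.0) for a, g in zip(props, mods)
        ]
        w0 = sum(weights)
        v = rand() * w0
        run = 0.0
        for j in range(n_rxn):
            run += weights[j]
            if v < run:
                break
        rec.flush(t_fire)
        t = t_fire
        _apply(state, rxns[j][3])  # init update == full nu (delay-free)
        rec.event(t, _FIRE, rxns[j][6])
    rec.finish(t_end)
    return traj


class _CallableModulator(Modulator):
    def __init__(self, fn):
        self._fn = fn

    def value(self, t):
        v = float(self._fn(t))
        if v < 0:
            raise ParameterError("modulator returned a negative value")
        return v


_ENGINES = {
    "rejection": simulate_rejection,
    "direct": simulate_direct,
    "ssa": simulate_ssa,
    "tv": simulate_time_varying,
}


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

def run_ensemble(
    system: ReactionSystem,
    n_runs: int,
    snapshot_times: Sequence[float],
    base_seed: int,
    engine: str = "rejection",
    t_end: float | None = None,
    rate_modulators: Mapping | None = None,
) -> np.ndarray:
    """Simulate ``n_runs`` independent trajectories, recording states on a grid.

    Returns an int array of shape ``(n_runs, len(snapshot_times), n_species)``.
    Run ``i`` uses child ``i`` of ``SeedSequence(base_seed)``, so ensembles
    are reproducible and trivially parallelizable.
    """
    if engine not in _ENGINES:
        raise ParameterError(f"unknown engine {engine!r}")
    snapshot_times = np.sort(np.asarray(snapshot_times, dtype=float))
    if t_end is None:
        t_end = float(snapshot_times[-1])
    ss = (base_seed if isinstance(base_seed, np.random.SeedSequence)
          else np.random.SeedSequence(base_seed))
    children = ss.spawn(int(n_runs))
    out = np.empty((n_runs, snapshot_times.size, len(system.species)), dtype=np.int64)
    sim = _ENGINES[engine]
    for i in range(n_runs):
        rng = np.random.default_rng(children[i])
        if engine == "tv":
            traj = sim(system, rate_modulators or {}, t_end, seed=rng,
                       snapshot_times=snapshot_times, record_events=False)
        else:
            traj = sim(system, t_end, seed=rng,
                       snapshot_times=snapshot_times, record_events=False)
        out[i] = traj.snapshots
    return out


def ensemble_distribution(
    trajectories: Sequence[Trajectory],
    t_query: float,
    species_subset: Sequence[int] | None = None,
) -> dict:
    """Normalized frequency table of states at ``t_query`` over an ensemble."""
    if len(trajectories) == 0:
        raise ParameterError("empty trajectory collection")
    states = np.stack([tr.state_at(t_query) for tr in trajectories])
    return distribution_from_states(states, species_subset)


def distribution_from_states(states: np.ndarray, species_subset=None) -> dict:
    """Frequency table from an ``(n_runs, n_species)`` state array."""
    states = np.asarray(states)
    if species_subset is not None:
        states = states[:, list(species_subset)]
    uniq, counts = np.unique(states, axis=0, return_counts=True)
    total = counts.sum()
    return {tuple(int(v) for v in row): c / total for row, c in zip(uniq, counts)}


def marginal_counts(states: np.ndarray, axis: int, n_max: int | None = None) -> np.ndarray:
    """Empirical marginal pmf of one species from an ensemble state array."""
    vals = np.asarray(states)[:, axis]
    hi = int(vals.max()) if n_max is None else n_max
    pmf = np.bincount(vals, minlength=hi + 1)[: hi + 1] / vals.size
    return pmf
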