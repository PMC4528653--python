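"""Reaction-system data model for delayed stochastic kinetics.

A reaction is classified by its delay handling:

``none``
    ordinary reaction; the full stoichiometric update ``nu`` is applied the
    instant the reaction fires.
``nonconsuming``
    delayed reaction whose entire update ``nu`` is applied when the delay
    completes (e.g. transcription: the gene is not consumed, the mRNA
    appears after maturation).
``consuming``
    delayed reaction with two update points: reactants are removed at
    initiation (``nu_r``) and products appear at completion (``nu_p``), as
    for a transport step where a molecule physically leaves one pool and
    later arrives in another.

The module also builds the two reference models used throughout the test
suite: a linear five-state conversion chain (and its exact two-species
abridgment with an Erlang first-passage delay) and an mRNA-maturation
transcription/translation model (and its abridgment with a delayed
transcription reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .delays import DelayDistribution, arrival_probability
from .errors import InvalidStateError, ParameterError, StateUnderflowError

__all__ = [
    "Reaction",
    "ReactionSystem",
    "PendingEvent",
    "mass_action_propensity",
    "apply_update",
    "build_five_state_chain",
    "build_mrna_maturation",
]

DELAY_CLASSES = ("none", "nonconsuming", "consuming")


@dataclass
class PendingEvent:
    """A delayed reaction initiated in the past, due to complete at ``due_time``.

    ``completion_update`` is the update vector applied at completion: ``nu``
    for a non-consuming reaction, ``nu_p`` for a consuming one.  A queue of
    these events is the process memory (the initial queue is the history the
    system starts with).
    """

    reaction_id: str
    due_time: float
    completion_update: np.ndarray | None = None


@dataclass
class Reaction:
    """A mass-action reaction with an optional delay.

    ``reactants`` and ``products`` map species names to non-negative integer
    stoichiometric counts.  The update vectors ``nu`` (or ``nu_r``/``nu_p``
    for consuming reactions) are bound against a species ordering when the
    reaction is placed in a :class:`ReactionSystem`.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    delay_class: str = "none"
    delay: DelayDistribution | None = None
    # bound by ReactionSystem
    nu: np.ndarray | None = field(default=None, repr=False, compare=False)
    nu_r: np.ndarray | None = field(default=None, repr=False, compare=False)
    nu_p: np.ndarray | None = field(default=None, repr=False, compare=False)
    reactant_pairs: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise ParameterError(f"reaction {self.id}: rate constant must be > 0")
        if self.delay_class not in DELAY_CLASSES:
            raise ParameterError(
                f"reaction {self.id}: delay class must be one of {DELAY_CLASSES}"
            )
        for side, name in ((self.reactants, "reactant"), (self.products, "product")):
            for sp, c in side.items():
                if int(c) != c or c < 0:
                    raise ParameterError(
                        f"reaction {self.id}: {name} count for {sp} must be a "
                        f"non-negative integer"
                    )
        if self.delay_class == "none":
            if self.delay is not None:
                raise ParameterError(
                    f"reaction {self.id}: non-delayed reaction must not carry a delay"
                )
        elif self.delay is None:
            raise ParameterError(f"reaction {self.id}: delayed reaction needs a delay law")

    @property
    def is_delayed(self) -> bool:
        return self.delay_class != "none"

    def _bind(self, index: Mapping[str, int], n_species: int) -> None:
        """Compute update vectors and propensity index pairs for a species order."""
        nu = np.zeros(n_species, dtype=np.int64)
        nu_r = np.zeros(n_species, dtype=np.int64)
        for sp, c in self.reactants.items():
            nu[index[sp]] -= c
            nu_r[index[sp]] -= c
        nu_p = nu - nu_r  # running total; finished below
        for sp, c in self.products.items():
            nu[index[sp]] += c
            nu_p[index[sp]] += c
        self.nu = nu
        if self.delay_class == "consuming":
            self.nu_r, self.nu_p = nu_r, nu_p
            assert np.array_equal(nu_r + nu_p, nu)
        else:
            self.nu_r = self.nu_p = None
        self.reactant_pairs = tuple((index[sp], int(c)) for sp, c in self.reactants.items() if c)


@dataclass
class ReactionSystem:
    """Species, reactions, initial state and initial pending-event history."""

    species: Sequence[str]
    reactions: Sequence[Reaction]
    initial_state: Sequence[int]
    initial_history: list[PendingEvent] = field(default_factory=list)
    time_origin: float = 0.0

    def __post_init__(self):
        self.species = list(self.species)
        if len(set(self.species)) != len(self.species):
            raise ParameterError("duplicate species names")
        self._index = {sp: i for i, sp in enumerate(self.species)}
        self.initial_state = np.asarray(self.initial_state, dtype=np.int64)
        if self.initial_state.shape != (len(self.species),):
            raise ParameterError(
                f"initial state has length {self.initial_state.size}, "
                f"expected {len(self.species)}"
            )
        if np.any(self.initial_state < 0):
            raise InvalidStateError("initial state must be componentwise non-negative")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate reaction ids")
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in self._index:
                    raise ParameterError(f"reaction {r.id} references unknown species {sp}")
            r._bind(self._index, len(self.species))
        by_id = {r.id: r for r in self.reactions}
        for ev in self.initial_history:
            if ev.reaction_id not in by_id:
                raise ParameterError(f"history references unknown reaction {ev.reaction_id}")
            rx = by_id[ev.reaction_id]
            if not rx.is_delayed:
                raise ParameterError(f"history event for non-delayed reaction {rx.id}")
            if ev.due_time <= self.time_origin:
                raise ParameterError("history due times must lie after the time origin")
            if ev.completion_update is None:
                ev.completion_update = rx.nu_p if rx.delay_class == "consuming" else rx.nu

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def has_delays(self) -> bool:
        return any(r.is_delayed for r in self.reactions)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


def mass_action_propensity(state: np.ndarray, reaction: Reaction) -> float:
    """Mass-action propensity: rate constant times falling factorials of the
    reactant copy numbers; zero when any reactant is exhausted."""
    state = np.asarray(state)
    if np.any(state < 0):
        raise InvalidStateError("state has a negative component")
    if reaction.reactant_pairs is None:
        raise ParameterError("reaction is not bound to a system (unknown species order)")
    a = reaction.rate_constant
    for i, c in reaction.reactant_pairs:
        x = int(state[i])
        for m in range(c):
            a *= x - m
        if a <= 0.0:
            return 0.0
    return float(a)


def apply_update(state: np.ndarray, update: np.ndarray) -> np.ndarray:
    """Elementwise state update; raises if any copy number would go negative."""
    out = np.asarray(state, dtype=np.int64) + np.asarray(update, dtype=np.int64)
    if np.any(out < 0):
        raise StateUnderflowError(f"update {update} drove state {state} negative")
    return out


# --------------------------------------------------------------------------
# reference models
# --------------------------------------------------------------------------

def build_five_state_chain(k: float, n_walkers: int, abridged: bool = False) -> ReactionSystem:
    """Linear five-state conversion chain 0 -> 1 -> 2 -> 3 -> 4, all rates ``k``.

    The full variant has five species and four ordinary unimolecular
    reactions.  The abridged variant keeps only the end states: a single
    consuming delayed reaction removes a state-0 walker at initiation (the
    0 -> 1 step, exponential waiting time) and delivers a state-4 walker
    after an Erlang(3, k) delay — the first-passage time of the lumped
    1 -> 4 sub-chain.
    """
    if k <= 0:
        raise ParameterError("rate k must be positive")
    if int(n_walkers) != n_walkers or n_walkers < 1:
        raise ParameterError("n_walkers must be a positive integer")
    n_walkers = int(n_walkers)
    if not abridged:
        species = [f"S{i}" for i in range(5)]
        reactions = [
            Reaction(f"R{i}{i + 1}", {f"S{i}": 1}, {f"S{i + 1}": 1}, k)
            for i in range(4)
        ]
        x0 = [n_walkers, 0, 0, 0, 0]
        return ReactionSystem(species, reactions, x0)
    delay = DelayDistribution.erlang(3, k)
    rxn = Reaction("R40", {"S0": 1}, {"S4": 1}, k, delay_class="consuming", delay=delay)
    return ReactionSystem(["S0", "S4"], [rxn], [n_walkers, 0])


def build_mrna_maturation(
    r: int,
    k_m: float = 1.0,
    k: float = 1.0,
    mu: float = 0.2,
    k_p: float = 1.0,
    mu_m: float = 0.2,
    mu_p: float = 0.2,
    abridged: bool = False,
    step_rates: Sequence[float] | None = None,
    step_death_rates: Sequence[float] | None = None,
) -> ReactionSystem:
    """Transcription/translation model with an ``r``-step mRNA maturation chain.

    Full variant: DNA transcribes a precursor mRNA_1 at rate ``k_m``; each
    precursor either matures one step (rate ``k``) or is degraded (rate
    ``mu``); mature mRNA is translated (``k_p``, catalytic) and degraded
    (``mu_m``); protein is degraded (``mu_p``).  DNA copy number is 1.

    Abridged variant: the maturation chain is replaced by a single delayed
    non-consuming transcription reaction producing mature mRNA with
    effective rate ``k_m * p`` — ``p`` the chain arrival probability
    ``(k/(k+mu))^r`` — and an Erlang(r, k+mu) first-passage delay.  DNA is
    implicit (the delayed reaction has constant propensity).  With
    ``step_rates``/``step_death_rates`` (length ``r`` each) the general
    distinct-rate chain is built instead, with a hypoexponential delay on
    the eigenvalue magnitudes ``k_i + mu_i``.
    """
    if int(r) != r or r < 1:
        raise ParameterError("chain length r must be a positive integer")
    r = int(r)
    for name, val in (("k_m", k_m), ("k", k), ("mu", mu), ("k_p", k_p),
                      ("mu_m", mu_m), ("mu_p", mu_p)):
        if val <= 0:
            raise ParameterError(f"rate {name} must be positive")
    general = step_rates is not None or step_death_rates is not None
    if general:
        if step_rates is None or step_death_rates is None:
            raise ParameterError("step_rates and step_death_rates must be given together")
        ks = np.asarray(step_rates, dtype=float)
        mus = np.asarray(step_death_rates, dtype=float)
        if ks.shape != (r,) or mus.shape != (r,):
            raise ParameterError("per-step rate vectors must have length r")
        if np.any(ks <= 0) or np.any(mus <= 0):
            raise ParameterError("per-step rates must be positive")
    else:
        ks = np.full(r, float(k))
        mus = np.full(r, float(mu))

    if not abridged:
        species = ["DNA"] + [f"mRNA_{i}" for i in range(1, r + 1)] + ["mRNA", "Protein"]
        reactions = [Reaction("R_tx", {"DNA": 1}, {"DNA": 1, "mRNA_1": 1}, k_m)]
        for i in range(1, r + 1):
            target = "mRNA" if i == r else f"mRNA_{i + 1}"
            reactions.append(
                Reaction(f"R_mat{i}", {f"mRNA_{i}": 1}, {target: 1}, float(ks[i - 1]))
            )
            reactions.append(
                Reaction(f"R_deg{i}", {f"mRNA_{i}": 1}, {}, float(mus[i - 1]))
            )
        reactions += [
            Reaction("R2", {"mRNA": 1}, {"mRNA": 1, "Protein": 1}, k_p),
            Reaction("R3", {"mRNA": 1}, {}, mu_m),
            Reaction("R4", {"Protein": 1}, {}, mu_p),
        ]
        x0 = [1] + [0] * (r + 2)
        return ReactionSystem(species, reactions, x0)

    lams = ks + mus  # absolute eigenvalues of the chain's transition matrix
    p = arrival_probability(ks, lams)
    if general and not np.allclose(lams, lams[0], rtol=1e-12):
        delay = DelayDistribution.hypoexponential(lams)
    else:
        delay = DelayDistribution.erlang(r, float(lams[0]))
    r1 = Reaction("R1", {}, {"mRNA": 1}, k_m * p, delay_class="nonconsuming", delay=delay)
    reactions = [
        r1,
        Reaction("R2", {"mRNA": 1}, {"mRNA": 1, "Protein": 1}, k_p),
        Reaction("R3", {"mRNA": 1}, {}, mu_m),
        Reaction("R4", {"Protein": 1}, {}, mu_p),
    ]
    return ReactionSystem(["mRNA", "Protein"], reactions, [0, 0])
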