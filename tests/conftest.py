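import numpy as np
import pytest

from dcme import (DelayDistribution, Reaction, ReactionSystem,
                  build_five_state_chain, build_mrna_maturation)

# paper-style reference parameterizations used across the suite
FIVE_STATE_K = 0.2
FIVE_STATE_N = 100
MRNA_R = 7
MRNA_RATES = dict(k_m=1.0, k=1.0, mu=0.2, k_p=1.0, mu_m=0.2, mu_p=0.2)


@pytest.fixture(scope="session")
def five_state_full():
    return build_five_state_chain(FIVE_STATE_K, FIVE_STATE_N)


@pytest.fixture(scope="session")
def five_state_abridged():
    return build_five_state_chain(FIVE_STATE_K, FIVE_STATE_N, abridged=True)


@pytest.fixture(scope="session")
def mrna_full():
    return build_mrna_maturation(MRNA_R, **MRNA_RATES)


@pytest.fixture(scope="session")
def mrna_abridged():
    return build_mrna_maturation(MRNA_R, **MRNA_RATES, abridged=True)


def make_tv_variant(abridged: ReactionSystem) -> ReactionSystem:
    """Replace the delayed production of the abridged mRNA model by an
    instantaneous reaction of the same rate; pairing it with the delay-CDF
    modulator reproduces the delayed dynamics exactly."""
    delayed = [r for r in abridged.reactions if r.is_delayed]
    assert len(delayed) == 1
    d = delayed[0]
    inst = Reaction(d.id, dict(d.reactants), dict(d.products), d.rate_constant)
    others = [
        Reaction(r.id, dict(r.reactants), dict(r.products), r.rate_constant)
        for r in abridged.reactions
        if not r.is_delayed
    ]
    return ReactionSystem(
        list(abridged.species), [inst] + others, abridged.initial_state.copy()
    )


def binomial_tolerance(p_a, p_b, n_a, n_b=None, z=3.0):
    """Agreement tolerance for two pmf estimates: z pooled binomial standard
    errors plus a one-count continuity allowance.  ``n_b=None`` marks the
    second table as deterministic (exact)."""
    pbar = 0.5 * (np.asarray(p_a) + np.asarray(p_b))
    var = pbar * (1.0 - pbar) / n_a
    cont = 1.0 / n_a
    if n_b is not None:
        var = var + pbar * (1.0 - pbar) / n_b
        cont = 1.0 / min(n_a, n_b)
    return z * np.sqrt(var) + cont


def pad_to(pmf, size):
    out = np.zeros(size)
    out[: len(pmf)] = pmf
    return out
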