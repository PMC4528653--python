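# dcme — delay chemical master equations

Stochastic chemical kinetics with delays: when a chain of elementary steps
(mRNA maturation, transport, polymerase elongation) is lumped into a single
reaction that completes after a random delay, the probability law of the
system is no longer the chemical master equation (CME) but its non-Markovian
extension, the **delay chemical master equation (DCME)**.  `dcme` is a
toolkit for simulating and — in the solvable cases — directly solving DCMEs:

- **Exact delay-SSA engines.**  The *rejection* method (discard a tentative
  waiting time whenever a scheduled delayed update pre-empts it) and the
  *direct* method (piecewise next-reaction density across the pending-update
  intervals, no rejections), plus a plain Gillespie SSA and an SSA for
  time-varying propensities `a_j(X) g_j(t)` with integrated-hazard
  inversion.  Delayed reactions follow the consuming / non-consuming
  classification: consuming reactions remove reactants at initiation and add
  products at completion; non-consuming reactions update everything at
  completion.
- **Delay-distribution algebra.**  First-passage laws of lumped linear
  chains: Erlang for identical step rates, hypoexponential for distinct
  ones, numerical convolution and tabulated laws otherwise; the compound CDF
  `T(t)` of initiation-plus-delay; the chain arrival probability
  `p = Π k_i / Π (k_i + μ_i)` under competing degradation.
- **Closed-form DCME solution.**  For `N` walkers undergoing a single
  delayed unimolecular reaction `S0 → S1` (rate `k`, delay PDF `τ`), the
  exact time-dependent law is multinomial over (source, product, in flight)
  with event probabilities `1 − F(t)`, `T(t)`, `F(t) − T(t)`, where
  `F(t) = 1 − e^{−kt}` and `T` is the CDF of `k e^{−kt} * τ(t)` — for any
  delay law.  Zero delay collapses it to a binomial with parameter
  `e^{−kt}`.
- **Direct numerical solution.**  For the abridged transcription/translation
  model (delayed mRNA production with constant propensity `k′_m`,
  translation, two decays) the DCME reduces exactly to a CME with one
  time-varying factor, `dP/dt = (A + F(t)B)P`.  A finite-state-projection
  (FSP) solver integrates this on a truncated copy-number lattice and
  certifies its own truncation error as the retained-mass deficit.  The
  matching steady-state protein law is evaluated from the probability
  generating function
  `G(z) = lim_{N→∞} exp(N[₁F₁(k_eq/(Nμ_p); μ_m/μ_p; (k_p/μ_p)(z−1)) − 1])`
  by two independent series routes that must agree to 1e-8.

Two reference systems are built in: a linear five-state conversion chain
(abridged to one consuming delayed reaction with an Erlang(3, k) first-
passage delay) and an mRNA-maturation transcription/translation model with
`r` precursor steps (abridged to one non-consuming delayed production with
an Erlang(r, k+μ) delay and effective rate `k_m (k/(k+μ))^r`).

## Worked example

Compare the closed-form multinomial with a delay-SSA ensemble for the
abridged five-state chain (`k = 0.2`, 100 walkers, Erlang(3, 0.2) delay):

```python
import numpy as np
from dcme import (DelayDistribution, build_five_state_chain, run_ensemble,
                  distribution_from_states, solution_table, compare_distributions)

system = build_five_state_chain(k=0.2, n_walkers=100, abridged=True)
states = run_ensemble(system, n_runs=100_000, snapshot_times=[12.0],
                      base_seed=20150049, engine="rejection")
empirical = distribution_from_states(states[:, 0, :])

table = solution_table(t=12.0, N=100, k=0.2,
                       delay=DelayDistribution.erlang(3, 0.2))
print(f"mean walkers still in state 0: {table.mean_source:.3f}")
print(f"mean walkers arrived in state 4: {table.mean_product:.3f}")
report = compare_distributions(empirical, table.as_dict(), n_p=100_000)
print(f"max |empirical - closed form|: {report.max_abs_diff:.2e}")
```

Output:

```
mean walkers still in state 0: 9.072
mean walkers arrived in state 4: 22.128
max |empirical - closed form|: 7.39e-04
```

The means are `100·e^{−0.2·12}` and `100·T₄₀(12)` (the Erlang(4, 0.2) CDF);
the per-state discrepancy of the 10⁵-run ensemble is at the few-10⁻⁴ level
expected from sampling noise alone.

The same models are exposed on the command line:

```sh
dcme model five-state --k 0.2 --n-walkers 100 --out five.yaml
dcme simulate --model five.yaml --engine rejection --t-end 12 --runs 10000 \
     --seed 1 --out run
dcme closed-form --n 100 --k 0.2 --delay erlang:3,0.2 --t 12 --out table.tsv
dcme fsp --model mrna.yaml --caps 9,14 --t-grid 0:20:1 --out fsp
dcme gf --k-eq 0.279 --b 1 --x-scale 5 --mu-p 0.2 --out pn.tsv
```

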