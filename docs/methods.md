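# Methods

## Process semantics

A reaction system is a list of species, mass-action reactions and an
optional pending-event history.  Reactions carry one of three delay classes:

- **none** — the stoichiometric update `ν = products − reactants` is applied
  when the reaction fires.
- **non-consuming** — the whole update is applied when the delay completes.
  Appropriate when the reactant is not sequestered by the ongoing process
  (transcription: the gene keeps firing while earlier transcripts mature).
- **consuming** — reactants are removed at initiation (`ν^r = −reactants`)
  and products added at completion (`ν^p = +products`), with
  `ν^r + ν^p = ν`.  Appropriate for transport-like processes where the
  molecule is physically absent while in transit.

The classification matters: the same stoichiometry with a different class
yields different dynamics (a consuming walker cannot initiate twice).
Propensities are standard mass-action with falling-factorial counting.
State-vector ordering is the declaration order of the species list; all
update vectors use it.

## Simulation engines

**Rejection method.**  Draw a tentative waiting time `Δ = ln(1/u)/a₀`.  If a
pending delayed update is due before `t + Δ`, the tentative time is
discarded: the simulation advances to the due time, applies the completion
update, recomputes propensities and redraws.  Otherwise the firing reaction
is chosen with probability `a_j/a₀` and its class-specific updates applied;
delayed reactions schedule their completion at `t + Δ + δ` with `δ` drawn
from the reaction's delay law.

**Direct method.**  With pending due times `T₁ < … < T_k` the propensities
are constant on each interval, so the next-firing hazard is piecewise
linear.  The engine finds the interval `i` with
`Σ_{j≤i}(T_j − T_{j−1}) a₀(X(T_{j−1})) ≤ ln(1/u) < Σ_{j≤i+1}(…)`, applies
the completions at `T₁…T_i` in due order, and fires at
`T_i + [ln(1/u) − Σ_{j≤i}…]/a₀(X(T_i))`.  No random number is ever
discarded.  Both engines are exact samplers of the same process; the suite
checks their distributional equivalence by two-sample chi-square.

**Time-varying SSA.**  For propensities `a_j(X)·g_j(t)` with deterministic
bounded modulators, the next event solves the integrated-hazard equation
`∫_t^{t+Δ} Σ_j a_j g_j(s) ds = ln(1/u)`.  Because the hazard integral is
monotone in `Δ` and capped by the horizon, the root is bracketed on
`[0, t_end − t]` and found by Brent's method (xtol 1e-12).  Modulators may
supply a closed-form time integral; the Erlang-CDF modulator uses
`∫₀^t F(s) ds = t − (1/β) Σ_{j=1}^{r} P(j, βt)` (regularized incomplete
gamma), and plain callables fall back to adaptive quadrature.

Tie-breaking and read-off conventions: simultaneous completions are applied
in queue-insertion order (additive updates make the final state
order-independent); when a completion coincides exactly with a sampled
firing time the completion is applied first; a state queried at time `t`
includes every event due at exactly `t`.  Ensembles seed run `i` with child
`i` of `numpy.random.SeedSequence(base_seed)`, making them reproducible and
embarrassingly parallel.

## Delay laws

The first passage through a linear chain of `r` irreversible exponential
steps is the convolution of the step densities: Erlang(r, β) when all rates
equal β, hypoexponential otherwise.  The hypoexponential density uses the
partial-fraction form for distinct rates; all-equal rates route to the
Erlang branch; mixed multiplicities are tabulated by trapezoid-rule
convolution on a uniform grid sized to mean + 12 standard deviations
(4096 points — Erlang(3, k) round-trips through this path to ~1e-6).
With per-step degradation μ_i the delay law conditions on arrival and the
*rate* is thinned by the arrival probability `p = Π k_i / Π (k_i + μ_i)`;
for a bidiagonal chain the eigenvalue magnitudes are `k_i + μ_i`.

The compound CDF `T(t)` of an Exp(k) initiation time plus an independent
delay has closed forms for zero delay (`F`), constant delay
(`1 − e^{−k(t−s)}` for `t ≥ s`), matching-rate Erlang (Erlang(r+1, k)) and
distinct-rate hypoexponential combinations; every other case is evaluated
by adaptive quadrature of `∫₀^t k e^{−ks} C_delay(t−s) ds` with absolute
tolerance 1e-11 — orders of magnitude below the few-10⁻⁴ scale at which the
closed form is compared with simulation.

## Closed-form multinomial solution

For `N` independent walkers on `S0 → S1` with rate `k` and any delay law,
the joint law of (n at source, m at product) at time `t` is multinomial with
cell probabilities `1 − F(t)`, `T(t)` and `F(t) − T(t)` (in flight).
Factorials are computed in log space (usable to N ~ 10⁴; a configurable cell
cap refuses larger dense tables).  Marginals are the corresponding
binomials; with zero delay the in-flight cell vanishes and the binomial
with parameter `e^{−kt}` is recovered.

## Finite state projection

The abridged transcription/translation model has a delayed production whose
propensity is constant (the gene count never changes), so the joint
probabilities in the DCME factor exactly and the delayed term becomes the
time-varying factor `k′_m F(t)` with `F` the maturation-delay CDF — the
DCME is a CME with one time-dependent coefficient.  The solver builds
`dP/dt = (A + F(t)B)P` on the lattice `{0..M_max} × {0..P_max}`: `A` holds
translation (`k_p M`), mRNA decay (`μ_m M`) and protein decay (`μ_p P`);
`B = k′_m (shift-in-M − I)`.  Every state keeps its full outflow on the
diagonal, while inflow terms exist only inside the lattice, so column sums
are zero in the interior and negative where outflow crosses the boundary:
retained mass can only decrease, and the deficit `1 − ΣP` is the standard
FSP error certificate, monotone in time.

Integration uses `scipy.solve_ivp` (BDF, rtol 1e-8, atol 1e-12) with the
generator itself as the analytic Jacobian; the operator is dense, which is
exact and fast at the ~10²–10³ states used here.  Marginals are *not*
renormalized — the leaked mass is reported separately.

### Truncation error at the reference caps — a documented discrepancy

At the reference parameterization (r = 7, μ = μ_m = μ_p = 0.2,
k = k_m = k_p = 1, start (0,0)) the stationary protein mean is
`(k′_m/μ_m)(k_p/μ_p) ≈ 6.98` with variance ≈ 24.  An independent 5000-run
SSA ensemble of the *full* maturation network puts `P(Protein > 14)` at
t = 20 near 3.8%.  Since the retained mass of an absorbing truncation can
never exceed the true probability of being inside it, 3.8% lower-bounds the
deficit of the (M ≤ 9, P ≤ 14) projection at t = 20; this solver computes
8.04%.  The often-quoted ~0.1% figure for these caps is therefore not
reachable at t = 20 — the deficit crosses 0.1% near t ≈ 11 — and most
plausibly refers to an earlier time or to a larger state space than the
plotting range.  The acceptance suite states the reference window and
reports the computed value exactly; cross-validation against simulation
uses caps (15, 60), for which the leakage over [0, 20] is below 1e-6.

## Steady-state generating function

The stationary protein pmf comes from
`G(z) = lim_{N→∞} exp(N[₁F₁(k_eq/(Nμ_p); b; x) − 1])` with
`b = μ_m/μ_p` and `x = (k_p/μ_p)(z−1)`.  Two independent routes are
evaluated and must agree to 1e-8:

1. the analytic limit `log G = (k_eq/μ_p) Σ_{j≥1} x^j / (j (b)_j)`
   ((b)_j the rising factorial), and
2. the large-N form with the ₁F₁ series expanded at `N = 10⁹` (a
   convergence check repeats the evaluation at 10N and requires the change
   to be no larger than the distance to the analytic limit).  N = 10⁶ is
   insufficient here: the O(1/N) bias of the Pochhammer ratio is ~10⁻⁶,
   above the dual-path agreement target.

Both routes produce the coefficients of `log G` as a polynomial in `z`
(binomial expansion of `(z−1)^j`, 100 terms — the tail is checked against a
2·x_scale radius bound), after which `P(n)` follows from the standard
power-series exponential recurrence `g_n = (1/n) Σ_m m l_m g_{n−m}`.
Default `n_max = 60` covers the reference parameters (mean ≈ 7) to ~1e-9
tail mass.

## What the validation does and does not show

The acceptance checks compare four routes to the same law — closed form,
FSP, and three statistically exact samplers — on the two reference systems.
Distributional agreement is decided by chi-square tests (two-sample between
ensembles, goodness-of-fit against deterministic references; bins with
expected count below 5 pooled) at a familywise level of 1% across all
pair/time/axis combinations — a per-bin "max z < 3" rule over ~900
correlated comparisons would fail about half of all seeds on pure sampling
noise while being *less* sensitive to systematic bias, which inflates many
bins at once.  Per-bin deviations against the 3-standard-error scale (with
a one-count continuity allowance) are still computed as diagnostics.
Ensemble sizes are 10⁵ for the
closed-form comparison and 10⁴ per engine for the four-way equivalence;
these sizes resolve discrepancies at the 10⁻³–10⁻⁴ probability scale.  All
inputs are the programmatically built reference models: the suite validates
the machinery (engines, delay algebra, solvers) exactly on the model class
it targets — linear/catalytic mass-action kinetics with state-independent
delayed production — and says nothing about bimolecular networks, feedback
(Hill-type) regulation, or delays with state-dependent laws, which are out
of scope.  The flawed early delay-SSA variant that updates reactants only at
delay completion (and so lets the same molecules re-initiate) is
deliberately not implemented.

## Limitations

- A generic numerical solver for the arbitrary multi-reaction DCME is not
  provided: the joint probability terms do not factor in general, which is
  precisely why the solvable special cases here are of interest.
- The FSP caps are fixed per call; there is no adaptive cap expansion.  The
  error certificate makes insufficient caps visible rather than invisible.
- Delay laws with atoms other than a single constant, and phase-type fits
  to empirical delay data, are not supported.
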