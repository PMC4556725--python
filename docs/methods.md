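# Methods

## Scope and state

`mfneuron` simulates p̄ interacting neuron populations.  Neuron *i* of
population α carries a potential `V` (mV for HH, dimensionless O(1) for
FHN), a synaptic proportion `y ∈ [0,1]`, and either a recovery variable `w`
(FitzHugh–Nagumo) or gating proportions `(n, m, h)` (Hodgkin–Huxley).  In
the sign-preserving conductance model each neuron additionally carries one
CIR conductance per target population, so the lumped per-population limit
state has dimension p̄² + 6p̄.  Time is in ms; every rate is in ms⁻¹.

Two interaction models are implemented: *simple* (maximal conductance =
constant mean J̄ plus white noise with amplitude σ_J, contributing both a
drift and a diffusion interaction) and *sign-preserving* (per-neuron CIR
conductances `dJ = θ(J̄−J)dt + σ_J √J dB`, which cannot go negative).  The
membrane drift is the cubic `−v³/3 + v − w` for FHN and the classic ionic
currents `(I − g_Na m³h(v−E_Na) − g_K n⁴(v−E_K) − g_L(v−E_L))/C_m` for HH.

## Structural hypotheses and their numerical verification

Well-posedness of both the particle systems and their mean-field limits
rests on four structural properties, which `validate_hypotheses` checks on
explicit grids rather than assuming:

1. **Noise envelope.**  χ is Lipschitz, nonnegative, and vanishes outside a
   compact subset of (0, 1).  Default: a trapezoid, zero outside
   [0.05, 0.95], one on [0.1, 0.9], linear on ramps of width 0.05
   (Lipschitz constant 20); a smooth `cosine_bump` (sin² profile) is
   selectable.  The construction is ours — only the support and regularity
   are dictated by the theory.  `peak = 0` is admitted as the degenerate
   "no channel noise" envelope used in deterministic comparisons.
2. **Coercivity.**  Channel rates satisfy ρ_x(v) ∧ ζ_x(v) ≥ ν > 0, so the
   argument of the Langevin square root, `ρ(1−x) + ζx`, is bounded below by
   ν on x ∈ [0, 1] and the diffusion coefficient is Lipschitz there.  The
   classic HH rates are evaluated at v clipped to [−100, 100] mV (membrane
   potentials outside that range are not physiological; the clipping makes
   the rates bounded Lipschitz on all of ℝ) and floored at ν = 10⁻³ ms⁻¹.
   User-supplied rates are taken as-is and violations are *reported*
   (ν̂ = grid minimum), never silently repaired.
3. **One-sided Lipschitz drift.**  `estimate_one_sided_lipschitz` computes
   the grid supremum of `(F(v,q)−F(v′,q))(v−v′)/(v−v′)² + M(v,v′)`.  For the
   cubic FHN drift with damping form `M = (|v|−|v′|)²/3` the supremum is 1,
   attained at pairs with v·v′ = 0.  At those pairs the exact value is 1
   for *any* floating-point grid point, so the quotient is accumulated in
   extended (80-bit) precision and rounded to float64 at the end; the
   returned constant is then exactly 1.0 on any grid containing 0.  Pairs
   with |v−v′| < 10⁻¹² are excluded to avoid 0/0.
4. **Boundary conditions.**  For every gate/synapse coefficient pair, the
   diffusion vanishes for x ∉ (0, 1) and the drift is ≥ 0 on {x ≤ 0} and
   ≤ 0 on {x ≥ 1}.  Grids extend over x ∈ [−0.5, 1.5] so the one-sided
   clauses are exercised away from the boundary, one scalar constrained
   coordinate at a time (all other coordinates act as environment).

## Time stepping

Explicit Euler–Maruyama on a uniform grid; `T/dt` must be an integer and
snapshot times are `k·dt·stride` exactly (no accumulation drift).  The CIR
conductances use the **full-truncation** scheme: drift and diffusion are
evaluated at `max(J, 0)` and the result floored at 0.  This preserves
nonnegativity for any parameter combination without assuming a Feller
condition.  The absolute value under the Langevin square root is retained
even though it is redundant in continuous time: a discretized state can
transiently sit outside [0, 1], where the absolute value prevents a NaN.

**Boundary policy.**  By default gate/synapse variables are *not* clamped:
with the default envelope and dt = 10⁻⁴ ms no sample in any shipped
experiment leaves [0, 1] (the empirical form of the almost-sure containment
property).  At coarser steps (10⁻³ ms) a per-step Gaussian increment can
occasionally jump across the envelope's support; such excursions are
counted and reported in `Trajectory.excursions`, never silently fixed.  A
post-step clamp to [0, 1] is available behind a flag for users who prefer
hard containment over an unbiased scheme.

**Noise organization.**  Increments come from counter-based Philox streams
keyed by `(seed, stream id, channel)`, where the stream id travels with the
neuron.  Consequences: runs are reproducible from the seed alone; chunked
generation is bit-identical to one-shot generation; permuting neurons
together with their ids permutes trajectories bit-exactly; and coupled
limit copies can consume *exactly* the increments of their partner neurons.
To make the empirical synaptic mean invariant under within-population
permutations at the bit level, the summands are sorted before summation
(floating-point addition is not commutative-associative across orderings;
sorting restores a canonical order at negligible cost).

## Mean-field solver

The law of the limit process enters its own dynamics only through
`s̄_α(t) = E[S_α(V_t)]` and `ȳ_α(t) = E[y_t]`, and the package represents the
law by exactly these two functionals — no path measures are stored.  Given
s̄, the mean synaptic proportion is computed in closed form
(variation of constants for the linear ODE `ȳ' = a_r s̄ (1−ȳ) − a_d ȳ`),
using cumulative trapezoidal quadrature for both nested integrals, which
keeps the cost linear in the grid and is second-order: halving dt divides
the error by ≈ 4, with max error ≈ 6·10⁻¹⁰ at dt = 10⁻⁴ against the
constant-s̄ closed form.  The result is clipped to [0, 1] to absorb
last-digit quadrature noise.  The exponential rescaling inside the formula
grows like `e^{(a_d + a_r max s̄) T}`; for horizons beyond T ≈ 500/(a_d+a_r)
a segmented evaluation would be needed (not implemented — the package
targets tens of milliseconds).

The Picard iteration alternates (i) ȳ from s̄ in closed form, (ii) an
ensemble of M independent limit copies per population driven by ȳ, (iii)
re-estimation of s̄ from the ensemble.  The same seed is reused in every
iteration (common random numbers), so the iteration is a deterministic map
and its residuals decrease geometrically instead of rattling at Monte-Carlo
noise level; fresh seeds are used only across outer replications.  The
starting guess is the constant path `E[S(V₀)]`.  An optional damping factor
(< 1) relaxes the s̄ update for stiff configurations; the default is
undamped.  Non-convergence within `max_iter` raises an error carrying the
residual history.

Because ȳ is *defined* through the closed form (which factorizes
`E[S(V)(1−y)] ≈ E[S(V)]E[1−y]`), the ensemble mean of y need not coincide
with it exactly; `simulate_limit_ensemble` reports the empirical ȳ so the
discrepancy is visible (≈ 2·10⁻² at the default parameters), without
adjudicating it.

## Coupling and the chaos scan

`simulate_coupled` advances the N-particle system and N limit copies in the
same loop: identical initial draws, identical increments per (neuron,
channel), and — in the sign-preserving model — the *same* CIR sample paths
(the copies' conductances are overwritten with the particles' after each
step, which is exact because both systems share the conductance SDE and its
driving noise).  The only difference between partner dynamics is empirical
synaptic mean vs. deterministic ȳ(t); when the interaction vanishes, the
difference is exactly zero at machine precision, a property the test suite
asserts.

The chaos error for one representative neuron per population is
`sup_k Σ_α |R^{i_α,N}_{t_k} − R̃^{i_α}_{t_k}|²` over the stored grid (stride
1 — the grid sup is the computable surrogate of the continuous-time sup),
where the squared norm sums *all* state components.  `chaos_scan` averages
this over independent replications (fresh initial conditions and noise per
replication), reports the standard error, √N·D̂_N, and the least-squares
log-log slope with a 1000-resample bootstrap CI.  One high-accuracy
mean-field solve (M = 10× the largest N by default) is shared across the
scan, and its Monte-Carlo standard error is reported alongside so the input
bias is visible; the theoretical R̃ uses the exact limit law, which we can
only approximate.

The scan defaults to the sign-preserving model, for which the coupling
construction is stated; the simple-model coupling is available as well.

**What the scan shows and does not show.**  In every configuration we ran,
D̂_N decreases with N and √N·D̂_N is bounded by its value at the smallest N —
consistent with the proven O(1/√N) rate.  The *measured* slope is typically
near −1 (the Lipschitz-like rate): the mean-reverting interaction appears
to converge faster than the guaranteed bound.  Two caveats: (i) the
distribution of the per-replication sup-error is heavy-tailed — it is
dominated by rare events in which a shared-noise pair fires a spike in one
system but not the other — so 32 replications leave sizable standard errors
on D̂_N, and seed-to-seed variability in the fitted slope is large (bootstrap
CIs of ± 0.3–0.5 are typical); (ii) when the empirical rate is steeper than
≈ N⁻¹, the max/min ratio of √N·D̂_N across a 16-fold range of N exceeds
small constants simply because convergence is *fast*, not because the
bound fails.

## Default parameters (ours, not from the theory)

The theory fixes no numeric values; the defaults were chosen once as a
representative excitable regime and are all overridable per config:

| Parameter | Default | Meaning |
|---|---|---|
| FHN `(a, b, c)` | (0.7, 0.8, 0.08) | classic excitable recovery dynamics |
| σ_V (FHN) | 0.3 | membrane noise, subthreshold at rest |
| sigmoid `(C, λ, δ)` (FHN) | (1, 1, 0) | activation at the upper branch |
| a_r, a_d | 1.0, 1.0 ms⁻¹ | synaptic rise/decay |
| V̄ (FHN, excitatory) | 1.0 | reversal above rest |
| J̄, σ_J, θ | 0.5, 0.2, 1.0 ms⁻¹ | CIR conductance mean/noise/reversion |
| HH conductances | (120, 36, 0.3) mS/cm², classic reversals | squid-axon set |
| sigmoid (HH) | (1, 0.2 mV⁻¹, −20 mV) | activation near spike onset |
| χ | trapezoid [0.05, 0.95], plateau [0.1, 0.9], peak 1 | unattenuated Langevin noise in the bulk |
| ν (rate floor) | 10⁻³ ms⁻¹ | coercivity bound for classic HH rates |

Initial laws (all i.i.d. within a population, finite moments): V₀ ~
N(−60, 5) mV for HH and N(−1.2, 0.3) for FHN — the rest point of the
classic FHN nullclines is (v, w) = (−1.199, −0.624), and starting on the
stable branch is the standard resting-state condition (starting astride the
unstable middle branch makes shared-noise pairs diverge at the saddle and
the coupling-error estimator needlessly heavy-tailed); w₀ ~ N(−0.62, 0.2);
y₀ and gates ~ Beta(2, 2) rescaled onto [0.1, 0.9]; J₀ ~ Gamma(shape 4,
mean J̄).  When a coupling has J̄ = σ_J = 0 the degenerate constant J₀ = 0
is used so that "zero interaction" means exactly zero: with any J₀ > 0 the
decaying CIR path would keep a nonzero kernel and the exact coupling
identity could not hold.  This is the one sanctioned exception to the
requirement that conductances start in (0, ∞).

## What the synthetic conditions do and do not show

All inputs are synthetic: the generator produces exactly the i.i.d.,
support-constrained initial conditions and the white-noise structure the
model assumes.  Passing tests therefore certify the *implementation* of the
models and the internal consistency of the limit/coupling machinery — they
do not certify that real neural tissue satisfies the hypotheses (chemical
synapses only, constant-in-N proportions, globally shared reversal
potentials, Langevin rather than jump channel noise, no conduction delays,
no spatial structure).  Exact channel (jump-process) simulation,
Fokker–Planck solvers, stationary laws, and adaptive time stepping are out
of scope.

## Numerical bookkeeping

* Determinism: every public simulation is a pure function of (spec, layout,
  initial state, seed, dt, stride); all seeds may be ints, tuples of ints,
  or `SeedSequence`-compatible entropy.
* Degenerate inputs: empty trajectories, empty grids, negative CIR inputs,
  mismatched grids, wrong index multiplicities, and incompatible N all
  raise with messages naming the offending quantity; NaN/overflow during
  stepping raises naming the neuron and component.
* Zero-coupling edges omitted from a config are filled in automatically;
  a `theta` given for the simple conductance model is rejected at load to
  prevent silent misconfiguration.
* Trajectories are stored as HDF5 (with provenance attributes: spec hash,
  seed, dt, scheme, clamp flag) plus a flat CSV export for small runs;
  reports serialize to JSON; mean-field paths to CSV via pandas.
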