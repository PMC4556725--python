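"""Solve the mean-field (McKean-Vlasov) limit by Monte-Carlo Picard iteration.

The limit law enters the dynamics only through two deterministic paths per
population: the mean synaptic activation sbar(t) = E[S(V_t)] and the mean
synaptic proportion ybar(t) = E[y_t], the latter given in closed form by a
variation-of-constants formula.  The fixed point is found by alternating the
closed form with an ensemble of independent limit copies under common random
numbers.
"""

from pathlib import Path

from mfneuron import load_config, picard_solve

spec, laws, options = load_config(Path(__file__).parent / "fhn_one_population.toml")

paths = picard_solve(spec, laws, T=5.0, dt=1e-3, M=1000, tol=1e-3, seed=options.seed)

print(f"converged in {paths.iterations} iterations; residual history:")
for k, r in enumerate(paths.residuals, start=1):
    print(f"  iteration {k}: sup-norm change {r:.2e}")
print(f"sbar(0) = {paths.sbar[0, 0]:.4f} -> sbar(T) = {paths.sbar[0, -1]:.4f}")
print(f"ybar(0) = {paths.ybar[0, 0]:.4f} -> ybar(T) = {paths.ybar[0, -1]:.4f}")
# The residuals decrease geometrically: the Picard map is an empirical
# contraction on the pair (sbar, ybar), mirroring the contraction argument
# that makes the limit system well posed.
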