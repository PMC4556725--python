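"""Check the structural hypotheses of a model configuration.

Loads the shipped one-population FitzHugh-Nagumo config and verifies
numerically: compact support of the noise envelope, coercivity of the
channel rates, sigmoid shape, the one-sided Lipschitz constant of the
membrane drift, and the boundary (invariance) conditions.
"""

from pathlib import Path

from mfneuron import load_config, validate_hypotheses

spec, laws, options = load_config(Path(__file__).parent / "fhn_one_population.toml")
report = validate_hypotheses(spec)

print(f"all hypotheses satisfied: {report.ok}")
print(f"chi support measured on the grid: {report.chi_support}"
      f"  (Lipschitz constant {report.chi_lipschitz:.0f})")
print(f"one-sided Lipschitz constant of the membrane drift: "
      f"{report.one_sided_L}")
print(f"boundary conditions (diffusion vanishes / drift inward): "
      f"{report.boundary_diffusion_ok} / {report.boundary_drift_ok}")
# The constant 1.0 for the cubic drift is exact: the supremum of the
# quotient with damping form (|v|-|v'|)^2/3 is attained whenever v*v' = 0.
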