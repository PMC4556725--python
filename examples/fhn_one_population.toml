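# One recurrently coupled FitzHugh-Nagumo population with sign-preserving
# (CIR) maximal conductances. Potentials are dimensionless O(1), time in ms.

[model]
conductance_model = "sign_preserving"

[population.exc]
model_kind = "FHN"
sigma_V = 0.3
a_r = 1.0
a_d = 1.0
proportion = 1.0
sigmoid = {C = 1.0, lam = 1.0, delta = 0.0}
fhn = {a = 0.7, b = 0.8, c = 0.08}

[interaction.exc.exc]
V_rev = 1.0
J_bar = 0.5
sigma_J = 0.2
theta = 1.0

[chi]
shape = "trapezoid"
lo = 0.05
hi = 0.95
peak = 1.0
ramp = 0.05

[init.exc]
V0 = {family = "normal", mu = -1.2, sigma = 0.3}
w0 = {family = "normal", mu = -0.62, sigma = 0.2}
y0 = {family = "beta_scaled", a = 2.0, b = 2.0, lo = 0.1, hi = 0.9}
J0 = {family = "gamma", shape = 4.0, scale = 0.125}

[run]
T = 10.0
dt = 0.001
N = 100
seed = 1
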