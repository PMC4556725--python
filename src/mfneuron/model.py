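"""Model parameterization and coefficient functions.

This module houses the full parameterization of a multi-population stochastic
neural network — membrane drifts (FitzHugh–Nagumo cubic or classic
Hodgkin–Huxley ionic currents), Langevin channel/synapse noise with a
compactly supported envelope ``chi``, sigmoidal synaptic activation, and the
synaptic-conductance model (constant-plus-white-noise or mean-reverting
square-root/CIR) — together with a numerical validator for the structural
hypotheses the well-posedness theory rests on:

* the noise envelope ``chi`` is Lipschitz with compact support inside (0, 1),
  so gating and synaptic proportions cannot diffuse across the boundary;
* channel opening/closing rates are bounded below by a positive constant
  ``nu`` (coercivity), so the argument of the Langevin square root stays
  positive on [0, 1];
* the membrane drift is one-sided Lipschitz in ``v`` (the cubic FHN nullcline
  is not globally Lipschitz but satisfies the one-sided condition with L = 1);
* drift/diffusion sign and vanishing conditions at the boundary of [0, 1]
  (inward-pointing drift, diffusion zero outside the open interval).

Units are mV for potentials and ms for time; every rate parameter is in 1/ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Mapping

import numpy as np

__all__ = [
    "SigmoidParams",
    "FHNParams",
    "HHDriftParams",
    "GateKinetics",
    "PopulationSpec",
    "InteractionSpec",
    "ChiFunction",
    "ModelSpec",
    "HypothesisReport",
    "sigmoid_eval",
    "chi_eval",
    "fhn_drift",
    "hh_membrane_drift",
    "gate_coefficients",
    "synapse_coefficients",
    "estimate_one_sided_lipschitz",
    "validate_hypotheses",
    "hh_rate",
    "V_CLIP",
]

#: Membrane potentials are clipped to this interval (mV) before evaluating
#: channel rate functions, making the rates bounded Lipschitz on all of R.
V_CLIP = (-100.0, 100.0)

#: Default lower bound (1/ms) enforced on channel rates (coercivity floor).
DEFAULT_NU = 1e-3


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the synaptic activation S(v) = C / (1 + exp(-lam(v - delta)))."""

    C: float = 1.0
    lam: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"sigmoid C must be > 0, got {self.C}")
        if not self.lam > 0:
            raise ValueError(f"sigmoid lam must be > 0, got {self.lam}")


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh–Nagumo recovery parameters: dw = c (v + a - b w) dt."""

    a: float = 0.7
    b: float = 0.8
    c: float = 0.08


@dataclass(frozen=True)
class HHDriftParams:
    """Maximal conductances (mS/cm^2), reversal potentials (mV), membrane
    capacitance (uF/cm^2) and applied current (uA/cm^2) of the classic
    Hodgkin–Huxley membrane equation."""

    g_na: float = 120.0
    e_na: float = 50.0
    g_k: float = 36.0
    e_k: float = -77.0
    g_l: float = 0.3
    e_l: float = -54.387
    c_m: float = 1.0
    i_app: float = 0.0

    def __post_init__(self) -> None:
        if not self.c_m > 0:
            raise ValueError("membrane capacitance c_m must be > 0")
        for name in ("g_na", "g_k", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _hh_classic_rates(gate: str, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classic Hodgkin–Huxley opening/closing rates (1/ms) for gate n, m or h.

    ``v`` is assumed already clipped; the 0/0 singularities of the n and m
    opening rates are removed by their analytic limits.
    """
    v = np.asarray(v, dtype=float)
    def _vtrap(x, scale):
        # x / (1 - exp(-x/scale)) with its analytic limit (= scale) at x = 0
        sing = np.abs(x) < 1e-7
        safe = np.where(sing, 1.0, x)
        return np.where(sing, scale, safe / (1.0 - np.exp(-safe / scale)))

    if gate == "n":
        alpha = 0.01 * _vtrap(v + 55.0, 10.0)
        beta = 0.125 * np.exp(-(v + 65.0) / 80.0)
    elif gate == "m":
        alpha = 0.1 * _vtrap(v + 40.0, 10.0)
        beta = 4.0 * np.exp(-(v + 65.0) / 18.0)
    elif gate == "h":
        alpha = 0.07 * np.exp(-(v + 65.0) / 20.0)
        beta = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    else:  # pragma: no cover - guarded by GateKinetics validation
        raise ValueError(f"unknown gate {gate!r}")
    return alpha, beta


@dataclass(frozen=True)
class GateKinetics:
    """Opening rate rho_x(v) and closing rate zeta_x(v) of one channel gate.

    ``kind`` selects the rate family:

    * ``"hh_classic"`` — the standard Hodgkin–Huxley alpha/beta expressions,
      evaluated at v clipped to [-100, 100] mV and floored at ``nu``;
    * ``"constant"`` — rho = rho_const, zeta = zeta_const (used for the
      boundary-invariance experiments with frozen rates);
    * ``"custom"`` — arbitrary callables (not serializable to config files).

    ``nu`` is the declared positive lower bound and ``r_max`` the declared
    upper bound of both rates on the clipped potential range.
    """

    kind: Literal["hh_classic", "constant", "custom"] = "hh_classic"
    nu: float = DEFAULT_NU
    r_max: float = 30.0
    rho_const: float | None = None
    zeta_const: float | None = None
    rho_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, compare=False)
    zeta_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError("rate floor nu must be > 0")
        if self.kind == "constant":
            if self.rho_const is None or self.zeta_const is None:
                raise ValueError("constant kinetics require rho_const and zeta_const")
        if self.kind == "custom" and (self.rho_fn is None or self.zeta_fn is None):
            raise ValueError("custom kinetics require rho_fn and zeta_fn")

    def rates(self, gate: str, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (rho(v), zeta(v)), evaluated at v clipped to [-100, 100] mV.

        The classic rates are additionally floored at ``nu`` (they decay
        exponentially in one tail, so the floor enforces the declared
        coercivity bound); user-supplied constant/custom rates are taken
        as-is and any coercivity violation is caught by validation.
        """
        v = np.clip(np.asarray(v, dtype=float), *V_CLIP)
        if self.kind == "hh_classic":
            rho, zeta = _hh_classic_rates(gate, v)
            return np.maximum(rho, self.nu), np.maximum(zeta, self.nu)
        if self.kind == "constant":
            return (
                np.full_like(v, float(self.rho_const)),
                np.full_like(v, float(self.zeta_const)),
            )
        return (
            np.asarray(self.rho_fn(v), dtype=float),
            np.asarray(self.zeta_fn(v), dtype=float),
        )


GATE_NAMES = ("n", "m", "h")


@dataclass(frozen=True)
class PopulationSpec:
    """All single-neuron parameters of one population.

    ``model_kind`` selects the membrane model: "FHN" carries the cubic drift
    and a deterministic recovery variable w; "HH" carries the ionic-current
    drift and three noisy gating variables (n, m, h).
    """

    label: str
    model_kind: Literal["FHN", "HH"] = "FHN"
    sigma_V: float = 0.3
    a_r: float = 1.0
    a_d: float = 1.0
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    fhn: FHNParams | None = None
    gates: Mapping[str, GateKinetics] | None = None
    hh_drift_params: HHDriftParams | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ("FHN", "HH"):
            raise ValueError(f"model_kind must be FHN or HH, got {self.model_kind!r}")
        if self.sigma_V < 0:
            raise ValueError("sigma_V must be >= 0")
        if not (self.a_r > 0 and self.a_d > 0):
            raise ValueError("synaptic rates a_r, a_d must be > 0")
        if self.model_kind == "FHN":
            if self.fhn is None:
                object.__setattr__(self, "fhn", FHNParams())
            if self.gates is not None or self.hh_drift_params is not None:
                raise ValueError("FHN population must not carry HH gates/drift params")
        else:
            if self.fhn is not None:
                raise ValueError("HH population must not carry FHN recovery params")
            if self.gates is None:
                object.__setattr__(
                    self, "gates", {x: GateKinetics() for x in GATE_NAMES}
                )
            if set(self.gates) != set(GATE_NAMES):
                raise ValueError("HH population requires kinetics for gates n, m, h")
            if self.hh_drift_params is None:
                object.__setattr__(self, "hh_drift_params", HHDriftParams())


@dataclass(frozen=True)
class InteractionSpec:
    """Synaptic coupling parameters for one ordered population pair (alpha, gamma):
    presynaptic population gamma acting on postsynaptic population alpha.

    ``conductance_model`` selects between the "simple" model (maximal
    conductance = constant mean plus white noise) and the "sign_preserving"
    model (per-neuron CIR conductance with reversion rate theta)."""

    V_rev: float = 0.0
    J_bar: float = 0.0
    sigma_J: float = 0.0
    theta: float | None = None
    conductance_model: Literal["simple", "sign_preserving"] = "sign_preserving"

    def __post_init__(self) -> None:
        if self.J_bar < 0:
            raise ValueError("J_bar must be >= 0")
        if self.sigma_J < 0:
            raise ValueError("sigma_J must be >= 0")
        if self.conductance_model == "sign_preserving":
            if self.theta is None or not self.theta > 0:
                raise ValueError("sign_preserving conductances require theta > 0")
        elif self.conductance_model == "simple":
            # theta is meaningless in the simple model; reject it to prevent
            # silent misconfiguration.
            if self.theta is not None:
                raise ValueError("theta is not a parameter of the simple conductance model")
        else:
            raise ValueError(f"unknown conductance_model {self.conductance_model!r}")


@dataclass(frozen=True)
class ChiFunction:
    """Noise envelope for gating/synaptic proportions.

    chi vanishes outside (lo, hi) with 0 < lo < hi < 1, is Lipschitz, and
    reaches ``peak`` in the bulk.  Two shapes are provided:

    * ``"trapezoid"`` (default): 0 outside [lo, hi], ``peak`` on
      [lo + ramp, hi - ramp], linear in between;
    * ``"cosine_bump"``: peak * sin^2(pi (x - lo)/(hi - lo)) on (lo, hi),
      a smooth alternative.
    """

    lo: float = 0.05
    hi: float = 0.95
    shape: Literal["trapezoid", "cosine_bump"] = "trapezoid"
    peak: float = 1.0
    ramp: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi < 1.0):
            raise ValueError("chi support must satisfy 0 < lo < hi < 1")
        if self.peak < 0:
            raise ValueError("chi peak must be >= 0 (0 switches channel noise off)")
        if self.shape == "trapezoid" and not (0 < self.ramp <= (self.hi - self.lo) / 2):
            raise ValueError("trapezoid ramp must lie in (0, (hi-lo)/2]")
        if self.shape not in ("trapezoid", "cosine_bump"):
            raise ValueError(f"unknown chi shape {self.shape!r}")

    @property
    def lipschitz_constant(self) -> float:
        if self.shape == "trapezoid":
            return self.peak / self.ramp
        return self.peak * np.pi / (self.hi - self.lo)

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        inside = (x > self.lo) & (x < self.hi)
        if self.shape == "trapezoid":
            up = (x - self.lo) / self.ramp
            down = (self.hi - x) / self.ramp
            val = self.peak * np.minimum(1.0, np.minimum(up, down))
        else:
            val = self.peak * np.sin(np.pi * (x - self.lo) / (self.hi - self.lo)) ** 2
        out = np.where(inside, val, 0.0)
        return out if out.ndim else float(out)


class SpecError(ValueError):
    """Raised when a model specification violates a structural invariant."""


@dataclass(frozen=True)
class ModelSpec:
    """A complete multi-population model: populations, interaction matrix,
    noise envelope and the fixed population proportions c_gamma.

    The lumped state of the limit system — potential, conductance block,
    synaptic variable, recovery and three gates per population — has dimension
    ``p_bar**2 + 6*p_bar`` where ``p_bar`` is the number of populations.
    """

    populations: tuple[PopulationSpec, ...]
    interactions: Mapping[tuple[str, str], InteractionSpec]
    chi: ChiFunction = field(default_factory=ChiFunction)
    proportions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.populations:
            raise SpecError("at least one population is required")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise SpecError("population labels must be unique")
        if self.proportions is None:
            c = 1.0 / len(labels)
            object.__setattr__(self, "proportions", {lab: c for lab in labels})
        if set(self.proportions) != set(labels):
            raise SpecError("proportions must be given for exactly the declared populations")
        c = np.array([self.proportions[lab] for lab in labels])
        if np.any(c <= 0):
            raise SpecError("every population proportion must be > 0")
        if abs(c.sum() - 1.0) > 1e-12:
            raise SpecError(f"population proportions must sum to 1, got {c.sum()}")
        for (a, g) in self.interactions:
            if a not in labels or g not in labels:
                raise SpecError(f"interaction ({a!r}, {g!r}) references unknown population")
        models = {e.conductance_model for e in self.interactions.values()}
        if len(models) > 1:
            raise SpecError("all interactions must use the same conductance model")
        # fill missing ordered pairs with zero-coupling edges
        model = models.pop() if models else "sign_preserving"
        full = dict(self.interactions)
        for a in labels:
            for g in labels:
                if (a, g) not in full:
                    full[(a, g)] = InteractionSpec(
                        V_rev=0.0, J_bar=0.0, sigma_J=0.0,
                        theta=1.0 if model == "sign_preserving" else None,
                        conductance_model=model,
                    )
        object.__setattr__(self, "interactions", full)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.populations)

    @property
    def p_bar(self) -> int:
        return len(self.populations)

    @property
    def state_dim(self) -> int:
        """Dimension of the lumped limit state: p_bar^2 + 6 p_bar."""
        p = self.p_bar
        return p * p + 6 * p

    @property
    def conductance_model(self) -> str:
        return next(iter(self.interactions.values())).conductance_model

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)

    def interaction_matrix(self, attr: str) -> np.ndarray:
        """(p_bar, p_bar) array of one interaction parameter, row = postsynaptic."""
        labs = self.labels
        return np.array(
            [[getattr(self.interactions[(a, g)], attr) or 0.0 for g in labs] for a in labs],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# coefficient functions
# ---------------------------------------------------------------------------

def sigmoid_eval(pop: PopulationSpec, v: np.ndarray | float) -> np.ndarray | float:
    """Synaptic activation S_alpha(v) = C / (1 + exp(-lam (v - delta))).

    Strictly increasing, valued in (0, C); represents the neurotransmitter
    concentration released by a presynaptic spike at potential v.
    """
    s = pop.sigmoid
    v = np.asarray(v, dtype=float)
    out = s.C / (1.0 + np.exp(-s.lam * (v - s.delta)))
    return out if out.ndim else float(out)


def chi_eval(chi: ChiFunction, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the noise envelope (zero outside its compact support)."""
    return chi(x)


def fhn_drift(pop: PopulationSpec, v, w):
    """FitzHugh–Nagumo membrane drift F(v, w) = -v^3/3 + v - w.

    Preserves extended-precision inputs (used by the one-sided Lipschitz
    estimator); integer inputs are promoted to float64.
    """
    v = np.asarray(v)
    w = np.asarray(w)
    if v.dtype.kind != "f":
        v = v.astype(float)
    if w.dtype.kind != "f":
        w = w.astype(float)
    out = -(v ** 3) / 3.0 + v - w
    return out if out.ndim else float(out)


def hh_membrane_drift(pop: PopulationSpec, v, n, m, h):
    """Classic Hodgkin–Huxley ionic-current membrane drift,

        C_m dV/dt = I_app - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K)
                    - g_L (V - E_L),

    returned as dV/dt (mV/ms).  Lipschitz in the gate variables for clipped v.
    """
    p = pop.hh_drift_params
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    h = np.asarray(h, dtype=float)
    i_ion = (
        p.g_na * m ** 3 * h * (v - p.e_na)
        + p.g_k * n ** 4 * (v - p.e_k)
        + p.g_l * (v - p.e_l)
    )
    out = (p.i_app - i_ion) / p.c_m
    return out if out.ndim else float(out)


def membrane_drift(pop: PopulationSpec, v, q):
    """Dispatch to the population's membrane drift.  ``q`` is w for FHN and
    an (..., 3) array of gates (n, m, h) for HH."""
    if pop.model_kind == "FHN":
        return fhn_drift(pop, v, q)
    q = np.asarray(q, dtype=float)
    return hh_membrane_drift(pop, v, q[..., 0], q[..., 1], q[..., 2])


def _langevin_pair(rho, zeta, x, chi):
    """Drift and diffusion of the Langevin channel/synapse SDE:
    drift = rho (1 - x) - zeta x, diffusion = sqrt(|rho (1 - x) + zeta x|) chi(x).

    The absolute value is retained under the root so transient discretized
    excursions outside [0, 1] cannot produce a NaN.
    """
    drift = rho * (1.0 - x) - zeta * x
    diff = np.sqrt(np.abs(rho * (1.0 - x) + zeta * x)) * chi(x)
    return drift, diff


def gate_coefficients(pop: PopulationSpec, chi: ChiFunction, x_name: str, v, x):
    """(drift, diffusion) of one Hodgkin–Huxley gating variable at (v, x)."""
    if pop.model_kind != "HH":
        raise ValueError("gate_coefficients requires an HH population")
    v = np.asarray(v, dtype=float)
    x = np.asarray(x, dtype=float)
    rho, zeta = pop.gates[x_name].rates(x_name, v)
    drift, diff = _langevin_pair(rho, zeta, x, chi)
    if drift.ndim:
        return drift, diff
    return float(drift), float(diff)


def synapse_coefficients(pop: PopulationSpec, chi: ChiFunction, v, y):
    """(drift, diffusion) of the synaptic variable: rho -> a_r S(v), zeta -> a_d."""
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = pop.a_r * sigmoid_eval(pop, v)
    drift, diff = _langevin_pair(rho, pop.a_d, y, chi)
    if np.ndim(drift):
        return drift, diff
    return float(drift), float(diff)


# ---------------------------------------------------------------------------
# hypothesis validation
# ---------------------------------------------------------------------------

def estimate_one_sided_lipschitz(
    F: Callable,
    M: Callable[[np.ndarray, np.ndarray], np.ndarray] | None,
    v_grid: np.ndarray,
    q_grid: np.ndarray | None = None,
    *,
    min_sep: float = 1e-12,
) -> float:
    """Grid supremum of the one-sided Lipschitz quotient

        (F(v, q) - F(v', q)) (v - v') / (v - v')^2 + M(v, v'),

    the smallest constant L such that
    (F(v,q) - F(v',q))(v - v') <= L (v-v')^2 - M(v,v') (v-v')^2 on the grid.

    For the FHN drift with the damping form M(v, v') = (|v| - |v'|)^2 / 3 the
    supremum is attained at pairs with v v' = 0 where its exact value is 1 for
    any floating-point grid point; the quotient is therefore accumulated in
    extended precision and the result rounded back to float64, so a grid
    containing 0 returns exactly 1.0.

    Pairs closer than ``min_sep`` are excluded to avoid 0/0.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("empty v_grid")
    if q_grid is None:
        q_grid = np.array([0.0])
    q_grid = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if q_grid.size == 0:
        raise ValueError("empty q_grid")
    v = v_grid.astype(np.longdouble)[:, None]
    vp = v_grid.astype(np.longdouble)[None, :]
    d = v - vp
    mask = np.abs(d) > min_sep
    denom = np.where(mask, d * d, 1.0)
    m_term = 0.0 if M is None else np.asarray(M(v, vp), dtype=np.longdouble)
    best = -np.inf
    for q in q_grid:
        fv = np.asarray(F(v, q), dtype=np.longdouble)
        fvp = np.asarray(F(vp, q), dtype=np.longdouble)
        quot = np.where(mask, (fv - fvp) * d / denom + m_term, -np.inf)
        best = max(best, float(np.float64(quot.max())))
    return best


@dataclass
class HypothesisReport:
    """Numerical verdicts for the structural hypotheses of one ModelSpec.

    Every flag is recomputed from the recorded grids and the spec alone;
    the report is a plain record, serializable to JSON.
    """

    chi_ok: bool
    chi_support: tuple[float, float]
    chi_lipschitz: float
    rates_ok: bool
    nu_hat: float | None
    sigmoid_ok: bool
    one_sided_L: dict[str, float]
    one_sided_M_form: str
    boundary_ok: bool
    boundary_diffusion_ok: bool
    boundary_drift_ok: bool
    v_grid: list[float] = field(repr=False, default_factory=list)
    x_grid: list[float] = field(repr=False, default_factory=list)

    @property
    def ok(self) -> bool:
        return self.chi_ok and self.rates_ok and self.sigmoid_ok and self.boundary_ok

    def to_json(self, **kw) -> str:
        d = asdict(self)
        d["ok"] = self.ok
        return json.dumps(d, **kw)


def validate_hypotheses(
    spec: ModelSpec,
    v_grid: np.ndarray | None = None,
    x_grid: np.ndarray | None = None,
) -> HypothesisReport:
    """Numerically check the structural hypotheses on a grid.

    Checks, per clause: compact support and nonnegativity of chi inside
    (0, 1); strict positivity (coercivity) of the channel rates with the
    measured floor nu_hat; sigmoid monotonicity and bounds; a finite grid
    estimate of the one-sided Lipschitz constant of each membrane drift; and
    the boundary conditions (diffusion vanishing outside (0, 1), drift
    pointing inward) for every gate and synapse coefficient pair.

    Failures are report entries, never exceptions.
    """
    if v_grid is None:
        v_grid = np.linspace(-100.0, 100.0, 401)
    if x_grid is None:
        x_grid = np.linspace(-0.5, 1.5, 401)
    v_grid = np.asarray(v_grid, dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)

    chi = spec.chi
    cx = np.asarray(chi(x_grid))
    inside01 = (x_grid > 0.0) & (x_grid < 1.0)
    chi_ok = (
        bool(np.all(cx[~inside01] == 0.0))
        and bool(np.all(cx >= 0.0))
        and np.isfinite(chi.lipschitz_constant)
        and float(np.asarray(chi(0.0))) == 0.0
        and float(np.asarray(chi(1.0))) == 0.0
    )
    support_pts = x_grid[cx > 0]
    chi_support = (
        (float(support_pts.min()), float(support_pts.max()))
        if support_pts.size
        else (np.nan, np.nan)
    )

    # coercivity of the channel rates (HH populations only)
    nu_hat: float | None = None
    rates_ok = True
    for pop in spec.populations:
        if pop.model_kind != "HH":
            continue
        for gate in GATE_NAMES:
            rho, zeta = pop.gates[gate].rates(gate, v_grid)
            g_min = float(np.minimum(rho, zeta).min())
            nu_hat = g_min if nu_hat is None else min(nu_hat, g_min)
    if nu_hat is not None:
        rates_ok = nu_hat > 0.0

    # strict monotonicity and the open bounds (0, C) saturate at double
    # precision far from the threshold; check them non-strictly on the full
    # grid and strictly near the threshold.
    sigmoid_ok = True
    for pop in spec.populations:
        s = np.asarray(sigmoid_eval(pop, v_grid))
        delta, lam = pop.sigmoid.delta, pop.sigmoid.lam
        near = delta + np.linspace(-5.0, 5.0, 11) / lam
        s_near = np.asarray(sigmoid_eval(pop, near))
        sigmoid_ok &= (
            bool(np.all(np.diff(s) >= 0))
            and bool(np.all((s >= 0) & (s <= pop.sigmoid.C)))
            and bool(np.all(np.diff(s_near) > 0))
        )

    # one-sided Lipschitz estimates per population
    one_sided: dict[str, float] = {}
    m_form = "FHN: M(v,v') = (|v|-|v'|)^2/3; HH: M = 0 on clipped grid"
    osl_grid = np.arange(-300, 301) / 100.0
    for pop in spec.populations:
        if pop.model_kind == "FHN":
            one_sided[pop.label] = estimate_one_sided_lipschitz(
                lambda v, q, _p=pop: fhn_drift(_p, v, q),
                lambda v, vp: (np.abs(v) - np.abs(vp)) ** 2 / 3.0,
                osl_grid,
            )
        else:
            # q fixed at mid-open gates; M = 0 (drift is Lipschitz in v there)
            q = np.array([0.3, 0.1, 0.6])
            one_sided[pop.label] = estimate_one_sided_lipschitz(
                lambda v, _q, _p=pop: hh_membrane_drift(_p, v, q[0], q[1], q[2]),
                None,
                np.linspace(V_CLIP[0], V_CLIP[1], 201),
            )

    # boundary conditions (shared with the invariance module's checker)
    from .invariance import check_boundary_conditions

    bflags = check_boundary_conditions(spec, x_grid=x_grid, v_grid=v_grid)
    diffusion_ok = all(f.diffusion_vanishes_ok for f in bflags)
    drift_ok = all(f.drift_sign_ok for f in bflags)

    return HypothesisReport(
        chi_ok=chi_ok,
        chi_support=chi_support,
        chi_lipschitz=float(chi.lipschitz_constant),
        rates_ok=bool(rates_ok),
        nu_hat=nu_hat,
        sigmoid_ok=bool(sigmoid_ok),
        one_sided_L=one_sided,
        one_sided_M_form=m_form,
        boundary_ok=bool(diffusion_ok and drift_ok),
        boundary_diffusion_ok=bool(diffusion_ok),
        boundary_drift_ok=bool(drift_ok),
        v_grid=[float(v_grid[0]), float(v_grid[-1]), float(len(v_grid))],
        x_grid=[float(x_grid[0]), float(x_grid[-1]), float(len(x_grid))],
    )


def hh_rate(gate: str, which: str, v):
    """Convenience access to the classic HH rates (clipped, unfloored).

    ``which`` is "rho" (opening, alpha) or "zeta" (closing, beta).
    """
    v = np.clip(np.asarray(v, dtype=float), *V_CLIP)
    alpha, beta = _hh_classic_rates(gate, v)
    return alpha if which == "rho" else beta
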