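"""Ready-made model specifications and default initial laws.

The underlying theory fixes the *structure* of the models but no numeric
parameter values; the defaults below are this package's own choices, made
once and documented in docs/methods.md.  FitzHugh–Nagumo populations use the
classic dimensionless parameter set (a=0.7, b=0.8, c=0.08) with an O(1)
potential scale; Hodgkin–Huxley populations use the classic squid-axon
conductances in mV/ms units.
"""

from __future__ import annotations

from .initial import InitLawSpec, Law, PopulationInitLaw
from .model import (
    ChiFunction,
    FHNParams,
    HHDriftParams,
    InteractionSpec,
    ModelSpec,
    PopulationSpec,
    SigmoidParams,
)

__all__ = [
    "fhn_population",
    "fhn_one_population",
    "fhn_two_population",
    "hh_one_population",
    "default_init_laws",
]


def fhn_population(label: str = "exc", *, sigma_V: float = 0.3,
                   a_r: float = 1.0, a_d: float = 1.0) -> PopulationSpec:
    """A FitzHugh–Nagumo population with the classic recovery parameters and
    a unit sigmoid centred at the unstable branch (delta = 0, lam = 1)."""
    return PopulationSpec(
        label=label,
        model_kind="FHN",
        sigma_V=sigma_V,
        a_r=a_r,
        a_d=a_d,
        sigmoid=SigmoidParams(C=1.0, lam=1.0, delta=0.0),
        fhn=FHNParams(a=0.7, b=0.8, c=0.08),
    )


def fhn_one_population(
    *,
    conductance_model: str = "sign_preserving",
    J_bar: float = 0.5,
    sigma_J: float = 0.2,
    theta: float | None = 1.0,
    V_rev: float = 1.0,
    sigma_V: float = 0.3,
) -> ModelSpec:
    """One recurrently coupled FitzHugh–Nagumo population.

    Defaults: excitatory reversal above the resting branch (V_rev = 1),
    mean maximal conductance J_bar = 0.5 with moderate noise sigma_J = 0.2,
    CIR reversion theta = 1/ms.  Set J_bar = sigma_J = 0 for the
    zero-interaction variant.
    """
    if conductance_model == "simple":
        theta = None
    return ModelSpec(
        populations=(fhn_population("exc", sigma_V=sigma_V),),
        interactions={
            ("exc", "exc"): InteractionSpec(
                V_rev=V_rev, J_bar=J_bar, sigma_J=sigma_J, theta=theta,
                conductance_model=conductance_model,
            )
        },
        chi=ChiFunction(),
        proportions={"exc": 1.0},
    )


def fhn_two_population(
    *,
    conductance_model: str = "sign_preserving",
    proportions=(0.8, 0.2),
) -> ModelSpec:
    """An excitatory/inhibitory pair of FitzHugh–Nagumo populations.

    The inhibitory reversal potential sits below the resting branch
    (V_rev = -2), the excitatory one above (V_rev = 1); cross-couplings are
    of the same magnitude as the recurrent ones.
    """
    theta = 1.0 if conductance_model == "sign_preserving" else None

    def edge(V_rev, J_bar):
        return InteractionSpec(
            V_rev=V_rev, J_bar=J_bar, sigma_J=0.2, theta=theta,
            conductance_model=conductance_model,
        )

    return ModelSpec(
        populations=(fhn_population("exc"), fhn_population("inh")),
        interactions={
            ("exc", "exc"): edge(1.0, 0.4),
            ("exc", "inh"): edge(-2.0, 0.4),
            ("inh", "exc"): edge(1.0, 0.4),
            ("inh", "inh"): edge(-2.0, 0.2),
        },
        chi=ChiFunction(),
        proportions={"exc": proportions[0], "inh": proportions[1]},
    )


def hh_one_population(
    *,
    conductance_model: str = "sign_preserving",
    J_bar: float = 0.3,
    sigma_J: float = 0.1,
    theta: float | None = 1.0,
    i_app: float = 8.0,
) -> ModelSpec:
    """One recurrently coupled Hodgkin–Huxley population (classic squid-axon
    parameters), with an excitatory synaptic reversal at 0 mV and a sigmoid
    threshold near spike onset (delta = -20 mV, lam = 0.2/mV)."""
    if conductance_model == "simple":
        theta = None
    pop = PopulationSpec(
        label="hh",
        model_kind="HH",
        sigma_V=1.0,
        a_r=1.1,
        a_d=0.19,
        sigmoid=SigmoidParams(C=1.0, lam=0.2, delta=-20.0),
        hh_drift_params=HHDriftParams(i_app=i_app),
    )
    return ModelSpec(
        populations=(pop,),
        interactions={
            ("hh", "hh"): InteractionSpec(
                V_rev=0.0, J_bar=J_bar, sigma_J=sigma_J, theta=theta,
                conductance_model=conductance_model,
            )
        },
        chi=ChiFunction(),
        proportions={"hh": 1.0},
    )


def default_init_laws(spec: ModelSpec) -> InitLawSpec:
    """Default initial laws satisfying the support/moment requirements.

    * V0: N(-60, 5) mV for HH populations (near rest); N(-1.2, 0.3) for FHN
      populations — the excitable rest point of the classic parameter set
      (a=0.7, b=0.8) is (v, w) = (-1.199, -0.624), and initializing on the
      stable branch rather than astride the unstable middle branch is the
      standard resting-state condition;
    * y0 and gates: Beta(2, 2) rescaled onto [0.1, 0.9];
    * J0: Gamma with mean J_bar (shape 4), per target population — or
      the degenerate constant 0 when that coupling has J_bar = sigma_J = 0;
    * w0: N(0, 0.5).
    """
    unit = Law("beta_scaled", {"a": 2.0, "b": 2.0, "lo": 0.1, "hi": 0.9})
    per = {}
    any_zero_J = False
    for a, lab in enumerate(spec.labels):
        pop = spec.population(lab)
        if pop.model_kind == "HH":
            V0 = Law("normal", {"mu": -60.0, "sigma": 5.0})
            w0 = Law("normal", {"mu": 0.0, "sigma": 0.5})
        else:
            V0 = Law("normal", {"mu": -1.2, "sigma": 0.3})
            w0 = Law("normal", {"mu": -0.62, "sigma": 0.2})
        J0 = {}
        for g in spec.labels:
            edge = spec.interactions[(lab, g)]
            if edge.J_bar > 0:
                J0[g] = Law("gamma", {"shape": 4.0, "scale": edge.J_bar / 4.0})
            else:
                J0[g] = Law("constant", {"value": 0.0})
                any_zero_J = True
        per[lab] = PopulationInitLaw(
            V0=V0, y0=unit, w0=w0, n0=unit, m0=unit, h0=unit, J0=J0,
        )
    return InitLawSpec(per_population=per, allow_zero_conductance=any_zero_J)
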