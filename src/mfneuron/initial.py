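"""Initial-condition laws and reproducible sampling.

The well-posedness and coupling results require initial conditions that are
i.i.d. within each population, with all moments finite for the potential and
conductances, proportions supported in [0, 1], and conductances supported in
(0, +inf).  This module describes such laws declaratively (so they serialize
to config files) and samples them deterministically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import ModelSpec
from .network import NetworkState, PopulationLayout

__all__ = ["Law", "PopulationInitLaw", "InitLawSpec", "sample_initial_conditions",
           "sample_population_init"]

_FAMILIES = ("normal", "uniform", "beta_scaled", "gamma", "lognormal", "constant")


@dataclass(frozen=True)
class Law:
    """One scalar distribution, given as a family name plus parameters.

    Families: normal(mu, sigma), uniform(lo, hi), beta_scaled(a, b, lo, hi)
    — a Beta(a, b) variable rescaled onto [lo, hi] —, gamma(shape, scale),
    lognormal(mu, sigma), constant(value).  All have moments of every order.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unsupported law family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "normal":
            return (-np.inf, np.inf)
        if self.family == "uniform":
            return (p["lo"], p["hi"])
        if self.family == "beta_scaled":
            return (p["lo"], p["hi"])
        if self.family == "gamma":
            return (0.0, np.inf)  # open at 0: P(X=0)=0
        if self.family == "lognormal":
            return (0.0, np.inf)
        return (p["value"], p["value"])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return rng.normal(p["mu"], p["sigma"], n)
        if self.family == "uniform":
            return rng.uniform(p["lo"], p["hi"], n)
        if self.family == "beta_scaled":
            return p["lo"] + (p["hi"] - p["lo"]) * rng.beta(p["a"], p["b"], n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], n)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], n)
        return np.full(n, float(p["value"]))


def _check_unit_support(law: Law, what: str) -> None:
    lo, hi = law.support()
    if lo < 0.0 or hi > 1.0:
        raise ValueError(f"{what} law must be supported in [0, 1], got {law}")


def _check_positive_support(law: Law, what: str, allow_zero_constant: bool) -> None:
    lo, hi = law.support()
    if law.family == "constant":
        v = law.params["value"]
        if v > 0 or (v == 0 and allow_zero_constant):
            return
        raise ValueError(f"{what} constant law must be > 0, got {v}")
    if lo < 0.0:
        raise ValueError(f"{what} law must be supported in (0, +inf), got {law}")


@dataclass(frozen=True)
class PopulationInitLaw:
    """Initial laws of one population: V0, y0, gates, w0 and the conductance
    row J0 (one law per target population, or one law for all)."""

    V0: Law
    y0: Law
    w0: Law
    n0: Law
    m0: Law
    h0: Law
    J0: Law | Mapping[str, Law]


@dataclass(frozen=True)
class InitLawSpec:
    """Per-population initial laws, validated against the support conditions:
    proportions in [0, 1], conductances in (0, +inf) — with the single
    degenerate exception J0 = 0 admitted for zero-coupling configurations."""

    per_population: Mapping[str, PopulationInitLaw]
    allow_zero_conductance: bool = False

    def __post_init__(self) -> None:
        for lab, laws in self.per_population.items():
            _check_unit_support(laws.y0, f"{lab}.y0")
            for g in ("n0", "m0", "h0"):
                _check_unit_support(getattr(laws, g), f"{lab}.{g}")
            j = laws.J0
            jlaws = j.values() if isinstance(j, Mapping) else [j]
            for jl in jlaws:
                _check_positive_support(
                    jl, f"{lab}.J0", allow_zero_constant=self.allow_zero_conductance
                )

    def for_population(self, label: str) -> PopulationInitLaw:
        return self.per_population[label]


_VAR_CODES = {"V": 0, "y": 1, "w": 2, "n": 3, "m": 4, "h": 5, "J": 6}


def _rng(seed, pop_index: int, var: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(0x1C, pop_index, _VAR_CODES[var]))
    return np.random.Generator(np.random.Philox(ss))


def sample_population_init(
    spec: ModelSpec, laws: InitLawSpec, label: str, n: int, seed
) -> dict[str, np.ndarray]:
    """n i.i.d. initial draws for one population, deterministic in the seed.

    Returns arrays V, y, w (zeros for HH), gates (n, 3; zeros for FHN) and
    J (n, p_bar).
    """
    a = spec.labels.index(label)
    pop = spec.population(label)
    pl = laws.for_population(label)
    out = {
        "V": pl.V0.sample(_rng(seed, a, "V"), n),
        "y": pl.y0.sample(_rng(seed, a, "y"), n),
    }
    if pop.model_kind == "FHN":
        out["w"] = pl.w0.sample(_rng(seed, a, "w"), n)
        out["gates"] = np.zeros((n, 3))
    else:
        out["w"] = np.zeros(n)
        gates = np.empty((n, 3))
        for gi, g in enumerate(("n", "m", "h")):
            gates[:, gi] = getattr(pl, f"{g}0").sample(_rng(seed, a, g), n)
        out["gates"] = gates
    J = np.empty((n, spec.p_bar))
    jrng = _rng(seed, a, "J")
    for g, glab in enumerate(spec.labels):
        jl = pl.J0[glab] if isinstance(pl.J0, Mapping) else pl.J0
        J[:, g] = jl.sample(jrng, n)
    out["J"] = J
    return out


def sample_initial_conditions(
    spec: ModelSpec, laws: InitLawSpec, layout: PopulationLayout, seed
) -> NetworkState:
    """One initial draw per neuron, i.i.d. within each population.

    Identical seeds yield identical states.  The draws are made per
    population in label order and scattered to the neuron positions, so the
    state only depends on the layout through the population sizes and the
    ordering of each population's members.
    """
    N, p = layout.N, spec.p_bar
    V = np.empty(N)
    y = np.empty(N)
    w = np.zeros(N)
    gates = np.zeros((N, 3))
    J = np.empty((N, p)) if spec.conductance_model == "sign_preserving" else None
    for lab in spec.labels:
        members = layout.members(lab)
        draws = sample_population_init(spec, laws, lab, members.size, seed)
        V[members] = draws["V"]
        y[members] = draws["y"]
        w[members] = draws["w"]
        gates[members] = draws["gates"]
        if J is not None:
            J[members] = draws["J"]
    state = NetworkState(t=0.0, V=V, y=y, w=w, gates=gates, J=J)
    # enforce the support invariants on the actual draw
    if np.any((y < 0) | (y > 1)) or np.any((gates < 0) | (gates > 1)):
        raise AssertionError("initial proportions escaped [0, 1]")
    if J is not None and np.any(J < 0):
        raise AssertionError("initial conductances escaped [0, +inf)")
    return state
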