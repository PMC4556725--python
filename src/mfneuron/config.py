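"""Configuration files: schema, validation, and round-trip serialization.

A single TOML (or YAML/JSON) document describes a full model: populations,
the interaction matrix, the noise envelope, population proportions, initial
laws and run options.  Validation collects *all* violations with their key
paths before raising, and :func:`dump_effective_config` re-emits the fully
resolved configuration (defaults filled in) as JSON, which
:func:`load_config` reads back bit-stably, so every run is reproducible from
its emitted effective config plus the seed.

Schema sketch (TOML)::

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
    V0 = {family = "normal", mu = 0.0, sigma = 0.4}
    # y0/n0/m0/h0/w0/J0 analogous; omitted laws fall back to the defaults

    [run]
    T = 20.0
    dt = 0.001
    N = 100
    seed = 1
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .initial import InitLawSpec, Law, PopulationInitLaw
from .model import (
    ChiFunction,
    FHNParams,
    GateKinetics,
    HHDriftParams,
    InteractionSpec,
    ModelSpec,
    PopulationSpec,
    SigmoidParams,
)

__all__ = ["ConfigError", "RunOptions", "load_config", "dump_effective_config"]


class ConfigError(ValueError):
    """Aggregated schema violations, each tagged with its key path."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  " + "\n  ".join(violations))


@dataclass(frozen=True)
class RunOptions:
    """Run parameters carried alongside the model in a config file."""

    T: float = 10.0
    dt: float = 1e-3
    N: int = 100
    seed: int = 0
    stride: int = 1
    M: int = 1000
    tol: float = 1e-3
    max_iter: int = 25


def _read(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        with open(path, "rb") as f:
            return tomllib.load(f)
    if suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as f:
            return yaml.safe_load(f)
    if suffix == ".json":
        with open(path) as f:
            return json.load(f)
    raise ConfigError([f"{path}: unsupported config format {suffix!r}"])


def _law_from(d: dict, path: str, errs: list[str]) -> Law | None:
    if not isinstance(d, dict) or "family" not in d:
        errs.append(f"{path}: a law needs a 'family' key")
        return None
    params = {k: v for k, v in d.items() if k != "family"}
    try:
        return Law(d["family"], params)
    except (ValueError, KeyError) as e:
        errs.append(f"{path}: {e}")
        return None


def load_config(path):
    """Parse and validate a config file.

    Returns ``(ModelSpec, InitLawSpec, RunOptions)`` or raises
    :class:`ConfigError` listing every violation with its key path.
    """
    doc = _read(path)
    errs: list[str] = []

    model_tbl = doc.get("model", {})
    cmodel = model_tbl.get("conductance_model", "sign_preserving")
    if cmodel not in ("simple", "sign_preserving"):
        errs.append(f"model.conductance_model: unknown value {cmodel!r}")

    pops_tbl = doc.get("population", {})
    if not pops_tbl:
        errs.append("population: at least one [population.<label>] is required")
    populations = []
    proportions = {}
    for lab, ptbl in pops_tbl.items():
        ppath = f"population.{lab}"
        kind = ptbl.get("model_kind", "FHN")
        proportions[lab] = float(ptbl.get("proportion", 1.0 / max(len(pops_tbl), 1)))
        try:
            sig = SigmoidParams(**ptbl.get("sigmoid", {}))
            fhn = FHNParams(**ptbl["fhn"]) if "fhn" in ptbl else None
            hhp = (
                HHDriftParams(**ptbl["hh_drift_params"])
                if "hh_drift_params" in ptbl
                else None
            )
            gates = None
            if "gates" in ptbl:
                gates = {
                    g: GateKinetics(**gtbl) for g, gtbl in ptbl["gates"].items()
                }
            populations.append(
                PopulationSpec(
                    label=lab,
                    model_kind=kind,
                    sigma_V=float(ptbl.get("sigma_V", 0.3)),
                    a_r=float(ptbl.get("a_r", 1.0)),
                    a_d=float(ptbl.get("a_d", 1.0)),
                    sigmoid=sig,
                    fhn=fhn,
                    gates=gates,
                    hh_drift_params=hhp,
                )
            )
        except (TypeError, ValueError) as e:
            errs.append(f"{ppath}: {e}")

    interactions = {}
    for a, row in doc.get("interaction", {}).items():
        if a not in pops_tbl:
            errs.append(f"interaction.{a}: unknown population {a!r}")
            continue
        for g, itbl in row.items():
            ipath = f"interaction.{a}.{g}"
            if g not in pops_tbl:
                errs.append(f"{ipath}: unknown population {g!r}")
                continue
            try:
                interactions[(a, g)] = InteractionSpec(
                    V_rev=float(itbl.get("V_rev", 0.0)),
                    J_bar=float(itbl.get("J_bar", 0.0)),
                    sigma_J=float(itbl.get("sigma_J", 0.0)),
                    theta=(float(itbl["theta"]) if "theta" in itbl else None),
                    conductance_model=cmodel,
                )
            except (TypeError, ValueError) as e:
                errs.append(f"{ipath}: {e}")

    chi = ChiFunction()
    if "chi" in doc:
        try:
            chi = ChiFunction(**doc["chi"])
        except (TypeError, ValueError) as e:
            errs.append(f"chi: {e}")

    spec = None
    if not errs:
        try:
            total = sum(proportions.values())
            proportions = {k: v / total for k, v in proportions.items()}
            spec = ModelSpec(
                populations=tuple(populations),
                interactions=interactions,
                chi=chi,
                proportions=proportions,
            )
        except ValueError as e:
            errs.append(f"model: {e}")

    laws = None
    if spec is not None:
        from .presets import default_init_laws

        defaults = default_init_laws(spec)
        per = {}
        for lab in spec.labels:
            base = defaults.for_population(lab)
            itbl = doc.get("init", {}).get(lab, {})
            kw = {}
            for var in ("V0", "y0", "w0", "n0", "m0", "h0", "J0"):
                if var not in itbl:
                    kw[var] = getattr(base, var)
                elif var == "J0" and "family" not in itbl[var]:
                    sub = {
                        g: _law_from(d, f"init.{lab}.J0.{g}", errs)
                        for g, d in itbl[var].items()
                    }
                    if all(l is not None for l in sub.values()):
                        kw[var] = sub
                else:
                    law = _law_from(itbl[var], f"init.{lab}.{var}", errs)
                    if law is not None:
                        kw[var] = law
                kw.setdefault(var, getattr(base, var))
            per[lab] = PopulationInitLaw(**kw)
        try:
            laws = InitLawSpec(
                per_population=per,
                allow_zero_conductance=defaults.allow_zero_conductance,
            )
        except ValueError as e:
            errs.append(f"init: {e}")

    run_tbl = doc.get("run", {})
    options = None
    try:
        options = RunOptions(**run_tbl)
    except TypeError as e:
        errs.append(f"run: {e}")

    if errs:
        raise ConfigError(errs)
    return spec, laws, options


def _law_to_dict(law: Law) -> dict:
    return {"family": law.family, **law.params}


def dump_effective_config(spec: ModelSpec, laws: InitLawSpec,
                          options: RunOptions, path) -> None:
    """Write the fully resolved configuration as JSON.

    ``load_config`` on the emitted file reproduces an identical
    (ModelSpec, InitLawSpec, RunOptions) triple.
    """
    doc: dict = {
        "model": {"conductance_model": spec.conductance_model},
        "population": {},
        "interaction": {},
        "chi": {
            "lo": spec.chi.lo, "hi": spec.chi.hi, "shape": spec.chi.shape,
            "peak": spec.chi.peak, "ramp": spec.chi.ramp,
        },
        "init": {},
        "run": {
            "T": options.T, "dt": options.dt, "N": options.N,
            "seed": options.seed, "stride": options.stride,
            "M": options.M, "tol": options.tol, "max_iter": options.max_iter,
        },
    }
    for pop in spec.populations:
        ptbl: dict = {
            "model_kind": pop.model_kind,
            "sigma_V": pop.sigma_V,
            "a_r": pop.a_r,
            "a_d": pop.a_d,
            "proportion": spec.proportions[pop.label],
            "sigmoid": {"C": pop.sigmoid.C, "lam": pop.sigmoid.lam,
                        "delta": pop.sigmoid.delta},
        }
        if pop.model_kind == "FHN":
            ptbl["fhn"] = {"a": pop.fhn.a, "b": pop.fhn.b, "c": pop.fhn.c}
        else:
            h = pop.hh_drift_params
            ptbl["hh_drift_params"] = {
                "g_na": h.g_na, "e_na": h.e_na, "g_k": h.g_k, "e_k": h.e_k,
                "g_l": h.g_l, "e_l": h.e_l, "c_m": h.c_m, "i_app": h.i_app,
            }
            ptbl["gates"] = {
                g: {"kind": k.kind, "nu": k.nu, "r_max": k.r_max,
                    **({"rho_const": k.rho_const, "zeta_const": k.zeta_const}
                       if k.kind == "constant" else {})}
                for g, k in pop.gates.items()
            }
        doc["population"][pop.label] = ptbl
    for (a, g), edge in spec.interactions.items():
        row = doc["interaction"].setdefault(a, {})
        row[g] = {"V_rev": edge.V_rev, "J_bar": edge.J_bar, "sigma_J": edge.sigma_J}
        if edge.theta is not None:
            row[g]["theta"] = edge.theta
    for lab in spec.labels:
        pl = laws.for_population(lab)
        itbl = {v: _law_to_dict(getattr(pl, v)) for v in ("V0", "y0", "w0", "n0", "m0", "h0")}
        j = pl.J0
        if isinstance(j, Law):
            itbl["J0"] = _law_to_dict(j)
        else:
            itbl["J0"] = {g: _law_to_dict(l) for g, l in j.items()}
        doc["init"][lab] = itbl
    with open(path, "w") as f:
        json.dump(doc, f, indent=2, sort_keys=True)
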