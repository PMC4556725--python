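"""Propagation-of-chaos diagnostics via the pathwise coupling construction.

The N-neuron system and N independent copies of the mean-field limit are
simulated with *identical* Brownian increments and identical initial
conditions, neuron by neuron.  In the sign-preserving model the limit copies
reuse the very same conductance sample paths as their partner neurons.  The
only difference between partner dynamics is the interaction: the particle
uses the empirical synaptic mean of its population, the limit copy uses the
deterministic mean-field input ybar_gamma(t).  The pathwise distance

    D_N = E[ sup_{t<=T} sum_alpha |R^{i_alpha,N}_t - Rtilde^{i_alpha}_t|^2 ],

with one representative neuron per population, measures the finite-N error;
the theory bounds sqrt(N) * D_N by a constant, i.e. D_N = O(1/sqrt(N)), to be
contrasted with the O(1/N) rate of globally Lipschitz interactions.
:func:`chaos_scan` estimates D_N over a range of N from independent
replications and fits the log-log scaling exponent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .meanfield import MeanFieldPaths, picard_solve
from .model import ModelSpec
from .network import (
    NetworkState,
    NoiseStreams,
    PopulationLayout,
    Trajectory,
    _SimContext,
    _draw_increments,
    _n_steps,
    _sorted_mean,
    _step,
    cir_step,
    spec_hash,
)

__all__ = ["CouplingRun", "CouplingReport", "simulate_coupled", "coupling_error", "chaos_scan"]


@dataclass
class CouplingRun:
    """One coupled simulation: particle system vs. limit copies, shared noise.

    ``diff_sq[k, i]`` is the full squared state distance
    |R^{i,N}_{t_k} - Rtilde^i_{t_k}|^2 (potential, conductance block,
    synaptic variable, recovery/gates).  Full trajectories of both systems
    are retained only when requested.
    """

    layout: PopulationLayout
    t: np.ndarray
    diff_sq: np.ndarray
    meanfield: MeanFieldPaths
    seed: object
    particle: Trajectory | None = None
    limit: Trajectory | None = None


def simulate_coupled(
    spec: ModelSpec,
    layout: PopulationLayout,
    meanfield: MeanFieldPaths,
    T: float,
    dt: float,
    seed,
    *,
    init_law=None,
    store_trajectories: bool = True,
    clamp: bool = False,
) -> CouplingRun:
    """Advance the N-neuron system and its coupled limit copies together.

    Both systems start from the same initial draw and consume the same
    Brownian increments per (neuron, channel); in the sign-preserving model
    the conductance paths are simulated once and shared, so
    Jtilde^{i,gamma} == J^{i,gamma} exactly.
    """
    n_steps = _n_steps(T, dt)
    grid = np.arange(n_steps + 1) * dt
    if meanfield.t.size != n_steps + 1 or not np.allclose(meanfield.t, grid):
        raise ValueError("mean-field paths are not defined on the simulation grid")
    if tuple(meanfield.labels) != spec.labels:
        raise ValueError("mean-field labels do not match spec populations")

    if init_law is None:
        from .presets import default_init_laws

        init_law = default_init_laws(spec)
    from .initial import sample_initial_conditions

    ctx = _SimContext(spec, layout)
    init = sample_initial_conditions(spec, init_law, layout, seed)
    part = init.copy()
    limit = init.copy()
    noise = NoiseStreams(seed)
    N, p = layout.N, spec.p_bar
    ybar_in = meanfield.ybar

    diff_sq = np.zeros((n_steps + 1, N))

    def record_diff(k):
        d = (part.V - limit.V) ** 2 + (part.y - limit.y) ** 2 + (part.w - limit.w) ** 2
        d += ((part.gates - limit.gates) ** 2).sum(axis=1)
        if part.J is not None:
            d += ((part.J - limit.J) ** 2).sum(axis=1)
        diff_sq[k] = d

    store = store_trajectories
    if store:
        def snap(state):
            return dict(V=state.V.copy(), y=state.y.copy(), w=state.w.copy(),
                        gates=state.gates.copy(),
                        J=None if state.J is None else state.J.copy())

        part_snaps, limit_snaps = [snap(part)], [snap(limit)]

    record_diff(0)
    chunk_size = 20_000
    done = 0
    while done < n_steps:
        nc = min(chunk_size, n_steps - done)
        dW = _draw_increments(ctx, noise, nc, dt)
        for s in range(nc):
            k = done + s
            dws = {c: a[s] for c, a in dW.items()}
            part = _step(ctx, part, dt, dws, clamp=clamp)
            limit = _limit_step(ctx, limit, dt, dws, ybar_in[:, k], clamp=clamp)
            if part.J is not None:
                # the coupled copies share the conductance sample paths exactly
                limit.J = part.J
            record_diff(k + 1)
            if store:
                part_snaps.append(snap(part))
                limit_snaps.append(snap(limit))
        done += nc

    def to_traj(snaps):
        return Trajectory(
            times=grid,
            V=np.array([s["V"] for s in snaps]),
            y=np.array([s["y"] for s in snaps]),
            w=np.array([s["w"] for s in snaps]),
            gates=np.array([s["gates"] for s in snaps]),
            J=None if snaps[0]["J"] is None else np.array([s["J"] for s in snaps]),
            provenance={"spec_hash": spec_hash(spec), "seed": repr(seed),
                        "dt": dt, "T": T, "stride": 1, "scheme": "coupled-euler-maruyama",
                        "clamp": clamp},
            excursions={},
        )

    return CouplingRun(
        layout=layout, t=grid, diff_sq=diff_sq, meanfield=meanfield, seed=seed,
        particle=to_traj(part_snaps) if store else None,
        limit=to_traj(limit_snaps) if store else None,
    )


def _limit_step(ctx: _SimContext, state: NetworkState, dt, dW, ybar_k, clamp=False):
    """One Euler–Maruyama step of the limit-copy dynamics: identical to the
    particle step except the interaction uses the deterministic ybar(t) and,
    in the sign-preserving model, the conductances are overwritten afterwards
    with the shared particle paths (so no CIR update is needed here)."""
    V, y, w, gates, J = state.V, state.y, state.w, state.gates, state.J

    F = ctx.membrane_drift(V, w, gates)
    K = J if ctx.sign_preserving else ctx.J_bar
    drift_V = F - ((V[:, None] - ctx.V_rev) * K * ybar_k[None, :]).sum(axis=1)
    V_new = V + drift_V * dt + ctx.sigma_V * dW["V"]
    if not ctx.sign_preserving and "B" in dW:
        V_new = V_new - (
            (V[:, None] - ctx.V_rev) * ctx.sigma_J * ybar_k[None, :] * dW["B"]
        ).sum(axis=1)

    S = ctx.sigmoid(V)
    drift_y = ctx.a_r * S * (1.0 - y) - ctx.a_d * y
    diff_y = np.sqrt(np.abs(ctx.a_r * S * (1.0 - y) + ctx.a_d * y)) * np.asarray(ctx.chi(y))
    y_new = y + drift_y * dt + diff_y * dW["y"]

    w_new = w + ctx.fhn_c * (V + ctx.fhn_a - ctx.fhn_b * w) * dt

    gates_new = gates
    if ctx.hh_pops:
        gates_new = gates.copy()
        for pidx, pop in ctx.hh_pops:
            i = ctx.layout.assignment == pidx
            Vi = V[i]
            for gi, gname in enumerate(("n", "m", "h")):
                rho, zeta = pop.gates[gname].rates(gname, Vi)
                x = gates[i, gi]
                drift = rho * (1.0 - x) - zeta * x
                diff = np.sqrt(np.abs(rho * (1.0 - x) + zeta * x)) * np.asarray(ctx.chi(x))
                gates_new[i, gi] = x + drift * dt + diff * dW[gname][i]

    if clamp:
        y_new = np.clip(y_new, 0.0, 1.0)
        gates_new = np.clip(gates_new, 0.0, 1.0)
    return NetworkState(t=state.t + dt, V=V_new, y=y_new, w=w_new,
                        gates=gates_new, J=J)


def coupling_error(run: CouplingRun, indices) -> float:
    """sup over the stored grid of sum_alpha |R^{i_alpha,N}_t - Rtilde^{i_alpha}_t|^2
    for one representative neuron per population."""
    indices = np.asarray(indices, dtype=np.intp)
    labels = run.layout.labels
    if indices.size != len(labels):
        raise ValueError("need exactly one index per population")
    pops = run.layout.assignment[indices]
    if sorted(pops.tolist()) != list(range(len(labels))):
        raise ValueError("indices must contain exactly one neuron of each population")
    return float(run.diff_sq[:, indices].sum(axis=1).max())


@dataclass
class CouplingReport:
    """Per-N chaos-error estimates and the fitted scaling exponent.

    ``D_hat[j]`` estimates D_N for ``N_list[j]`` from ``replications``
    independent coupled runs (mean over runs), ``se`` its standard error,
    and ``sqrtN_D = sqrt(N) * D_hat`` the bounded surrogate of the theoretical
    constant.  ``slope`` is the least-squares slope of log D_hat vs log N
    with a nonparametric-bootstrap confidence interval (None when some D_hat
    vanishes, e.g. for zero interaction).
    """

    N_list: list[int]
    D_hat: np.ndarray
    se: np.ndarray
    sqrtN_D: np.ndarray
    slope: float | None
    slope_ci: tuple[float, float] | None
    replications: int
    meanfield_sbar_se: float
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"N": self.N_list, "D_hat": self.D_hat, "se": self.se,
             "sqrtN_D": self.sqrtN_D}
        )

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "N_list": list(self.N_list),
                "D_hat": self.D_hat.tolist(),
                "se": self.se.tolist(),
                "sqrtN_D": self.sqrtN_D.tolist(),
                "slope": self.slope,
                "slope_ci": list(self.slope_ci) if self.slope_ci else None,
                "replications": self.replications,
                "meanfield_sbar_se": self.meanfield_sbar_se,
                "provenance": self.provenance,
            },
            **kw,
        )


def _fit_slope(N_arr, D):
    x = np.log(np.asarray(N_arr, dtype=float))
    yv = np.log(np.asarray(D, dtype=float))
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return float(coef[0])


def chaos_scan(
    spec: ModelSpec,
    N_list,
    replications: int,
    T: float,
    dt: float,
    base_seed: int,
    *,
    init_law=None,
    M: int | None = None,
    picard_tol: float = 2e-3,
    n_bootstrap: int = 1000,
) -> CouplingReport:
    """Estimate the chaos error D_N over a range of N and fit its scaling.

    One high-accuracy mean-field solve (M copies, default 10x the largest N)
    is shared across the whole scan; its Monte-Carlo standard error is
    reported alongside so the input bias is visible.  Each replication is an
    independent draw of all initial conditions and noise streams, seeded from
    (base_seed, N, replication).
    """
    N_list = sorted(int(n) for n in N_list)
    for N in N_list:
        PopulationLayout.from_proportions(spec, N)  # raises if incompatible
    if init_law is None:
        from .presets import default_init_laws

        init_law = default_init_laws(spec)
    if M is None:
        M = 10 * max(N_list)

    mf = picard_solve(spec, init_law, T, dt, M=M, tol=picard_tol, seed=(base_seed, 0))

    D = np.empty((len(N_list), replications))
    for j, N in enumerate(N_list):
        layout = PopulationLayout.from_proportions(spec, N)
        indices = np.array([layout.members(lab)[0] for lab in spec.labels])
        for r in range(replications):
            run = simulate_coupled(
                spec, layout, mf, T, dt, seed=(base_seed, 1 + j, r),
                init_law=init_law, store_trajectories=False,
            )
            D[j, r] = coupling_error(run, indices)

    D_hat = D.mean(axis=1)
    se = D.std(axis=1, ddof=1) / np.sqrt(replications)
    sqrtN_D = np.sqrt(np.asarray(N_list, dtype=float)) * D_hat

    slope = slope_ci = None
    if np.all(D_hat > 0):
        slope = _fit_slope(N_list, D_hat)
        rng = np.random.default_rng(np.random.SeedSequence((base_seed, 0xB00)))
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, replications, size=replications)
            Db = D[:, idx].mean(axis=1)
            boots[b] = _fit_slope(N_list, Db) if np.all(Db > 0) else np.nan
        boots = boots[np.isfinite(boots)]
        if boots.size:
            slope_ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return CouplingReport(
        N_list=N_list, D_hat=D_hat, se=se, sqrtN_D=sqrtN_D,
        slope=slope, slope_ci=slope_ci, replications=replications,
        meanfield_sbar_se=(
            float(np.max(mf.sbar_se_T)) if mf.sbar_se_T is not None else float("nan")
        ),
        provenance={
            "spec_hash": spec_hash(spec), "base_seed": base_seed, "T": T,
            "dt": dt, "M": M, "picard_iterations": mf.iterations,
        },
    )
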