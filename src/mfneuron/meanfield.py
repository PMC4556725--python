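"""McKean–Vlasov mean-field limit of the neuron networks.

As the population sizes grow, the pairwise synaptic interaction converges to
a deterministic coupling through the expected synaptic proportion
E[y_t^gamma] of each population.  The limit law is characterized as the fixed
point of a map Phi that sends candidate input paths to the law of the
decoupled SDE driven by them.  Only two path functionals of the law enter the
dynamics, and they are the representation used here:

* ``sbar_alpha(t) = E[S_alpha(V_t^alpha)]`` — the mean synaptic activation;
* ``ybar_alpha(t) = E[y_t^alpha]`` — the mean synaptic proportion, which
  satisfies the *linear* ODE  dybar/dt = a_r sbar(t) (1 - ybar) - a_d ybar
  and hence has the closed variation-of-constants form implemented by
  :func:`ybar_from_sbar` (the diffusion of y plays no role in the mean).

The fixed point is computed by a Monte-Carlo Picard iteration: given sbar,
compute ybar in closed form, drive an ensemble of independent limit copies
with it, and re-estimate sbar from the ensemble, under common random numbers
so the iteration is a deterministic map for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import ModelSpec, SpecError
from .network import NoiseStreams, cir_step, _n_steps

__all__ = [
    "MeanFieldPaths",
    "LimitEnsemble",
    "ybar_from_sbar",
    "simulate_limit_ensemble",
    "picard_solve",
    "PicardNonConvergence",
]


@dataclass
class MeanFieldPaths:
    """Deterministic input paths of the mean-field dynamics on a uniform grid.

    ``sbar[a, k]`` and ``ybar[a, k]`` hold sbar_alpha(t_k) and ybar_alpha(t_k)
    for population index a.  ``residuals`` records the Picard residual
    history when the paths come from :func:`picard_solve`.
    """

    t: np.ndarray
    labels: tuple[str, ...]
    sbar: np.ndarray
    ybar: np.ndarray
    iterations: int = 0
    residuals: list = field(default_factory=list)
    sbar_se_T: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sbar = np.atleast_2d(np.asarray(self.sbar, dtype=float))
        self.ybar = np.atleast_2d(np.asarray(self.ybar, dtype=float))
        if self.sbar.shape != (len(self.labels), self.t.size):
            raise ValueError("sbar shape must be (p_bar, len(t))")
        if self.ybar.shape != self.sbar.shape:
            raise ValueError("ybar shape must match sbar")

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        for a, lab in enumerate(self.labels):
            data[f"sbar_{lab}"] = self.sbar[a]
            data[f"ybar_{lab}"] = self.ybar[a]
        return pd.DataFrame(data)


@dataclass
class LimitEnsemble:
    """M i.i.d. copies per population of the limit SDE driven by fixed paths.

    Stores the empirical estimates of the path functionals (with standard
    errors at the final time), the terminal samples for distributional
    checks, and optionally the full V/y paths.
    """

    t: np.ndarray
    labels: tuple[str, ...]
    M: int
    sbar_hat: np.ndarray
    ybar_hat: np.ndarray
    sbar_se_T: np.ndarray
    V_T: dict[str, np.ndarray]
    y_T: dict[str, np.ndarray]
    V_paths: dict[str, np.ndarray] | None = None
    y_paths: dict[str, np.ndarray] | None = None


def ybar_from_sbar(a_r: float, a_d: float, y0_mean: float,
                   sbar: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Mean synaptic proportion from the mean activation path, in closed form.

    Solves dybar/dt = a_r sbar(t) (1 - ybar) - a_d ybar, ybar(0) = y0_mean,
    via the variation-of-constants formula

        ybar(t) = e^{-a_d t - A(t)} [ y0 + int_0^t a_r sbar(s) e^{a_d s + A(s)} ds ],
        A(t) = a_r int_0^t sbar,

    with trapezoidal quadrature for both integrals (cumulative, so the cost
    is linear in the grid size).  Output lies in [0, 1] whenever
    y0_mean is in [0, 1] and sbar >= 0.
    """
    sbar = np.asarray(sbar, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if sbar.shape != grid.shape:
        raise ValueError("sbar and grid must have the same shape")
    if np.any(sbar < 0):
        raise ValueError("sbar must be nonnegative")
    if not 0.0 <= y0_mean <= 1.0:
        raise ValueError("y0_mean must lie in [0, 1]")
    A = a_r * cumulative_trapezoid(sbar, grid, initial=0.0)
    expo = a_d * grid + A
    inner = cumulative_trapezoid(a_r * sbar * np.exp(expo), grid, initial=0.0)
    ybar = np.exp(-expo) * (y0_mean + inner)
    return np.clip(ybar, 0.0, 1.0)


def _pop_init_draws(spec, init_law, label, M, seed):
    """i.i.d. initial draws for one population (delegates to initial laws)."""
    from .initial import sample_population_init

    return sample_population_init(spec, init_law, label, M, seed)


def simulate_limit_ensemble(
    spec: ModelSpec,
    input_paths: MeanFieldPaths,
    M: int,
    T: float,
    dt: float,
    seed,
    *,
    init_law=None,
    store_paths: bool = False,
    id_offset: int = 1_000_000,
) -> LimitEnsemble:
    """Simulate M independent copies of the limit SDE per population.

    Each copy follows the decoupled dynamics in which the interaction uses
    the deterministic input ybar_gamma(t) from ``input_paths`` in place of
    the expectation; the diffusion of y itself plays no role in the mean but
    is simulated in full.  In the sign-preserving model every copy carries
    its own CIR conductance vector.  Copies are driven by independent streams
    keyed (id_offset + copy index, channel), reproducible from the seed.
    """
    if init_law is None:
        from .presets import default_init_laws

        init_law = default_init_laws(spec)
    n_steps = _n_steps(T, dt)
    grid = np.arange(n_steps + 1) * dt
    if input_paths.t.size != n_steps + 1 or not np.allclose(input_paths.t, grid):
        raise ValueError("input_paths grid does not match the simulation grid")

    noise = NoiseStreams(seed)
    p = spec.p_bar
    labels = spec.labels
    ybar_in = input_paths.ybar
    sign_preserving = spec.conductance_model == "sign_preserving"

    sbar_hat = np.empty((p, n_steps + 1))
    ybar_hat = np.empty((p, n_steps + 1))
    sbar_se_T = np.empty(p)
    V_T: dict[str, np.ndarray] = {}
    y_T: dict[str, np.ndarray] = {}
    V_paths = {} if store_paths else None
    y_paths = {} if store_paths else None

    root = np.sqrt(dt)
    for a, lab in enumerate(labels):
        pop = spec.population(lab)
        ids = np.arange(id_offset + a * M, id_offset + (a + 1) * M)
        draws = _pop_init_draws(spec, init_law, lab, M, seed)
        V = draws["V"].copy()
        y = draws["y"].copy()
        w = draws["w"].copy()
        gates = draws["gates"].copy()
        J = draws["J"].copy() if sign_preserving else None

        V_rev = spec.interaction_matrix("V_rev")[a]
        J_bar = spec.interaction_matrix("J_bar")[a]
        sigma_J = spec.interaction_matrix("sigma_J")[a]
        theta = spec.interaction_matrix("theta")[a]
        is_hh = pop.model_kind == "HH"

        def record(k):
            from .model import sigmoid_eval

            S = np.asarray(sigmoid_eval(pop, V))
            sbar_hat[a, k] = S.mean()
            ybar_hat[a, k] = y.mean()
            if k == n_steps:
                sbar_se_T[a] = S.std(ddof=1) / np.sqrt(M)
            if store_paths:
                V_store[k] = V
                y_store[k] = y

        if store_paths:
            V_store = np.empty((n_steps + 1, M))
            y_store = np.empty((n_steps + 1, M))
        record(0)

        # pre-draw increments in chunks to bound memory
        chunk_size = max(1, min(20_000, n_steps))
        done = 0
        from .model import sigmoid_eval, hh_membrane_drift

        while done < n_steps:
            nc = min(chunk_size, n_steps - done)
            dWV = noise.block(ids, "V", nc) * root
            dWy = noise.block(ids, "y", nc) * root
            dWg = (
                {g: noise.block(ids, g, nc) * root for g in ("n", "m", "h")}
                if is_hh
                else None
            )
            dB = None
            if sign_preserving or np.any(sigma_J > 0):
                dB = np.empty((nc, M, p))
                for g in range(p):
                    dB[:, :, g] = noise.block(ids, f"B:{g}", nc) * root
            for s in range(nc):
                k = done + s  # current grid index
                yb = ybar_in[:, k]  # (p,)
                if pop.model_kind == "FHN":
                    F = -(V ** 3) / 3.0 + V - w
                else:
                    F = np.asarray(
                        hh_membrane_drift(pop, V, gates[:, 0], gates[:, 1], gates[:, 2])
                    )
                K = J if sign_preserving else J_bar[None, :]
                drift_V = F - ((V[:, None] - V_rev[None, :]) * K * yb[None, :]).sum(axis=1)
                V_new = V + drift_V * dt + pop.sigma_V * dWV[s]
                if not sign_preserving and dB is not None:
                    V_new = V_new - (
                        (V[:, None] - V_rev[None, :]) * sigma_J[None, :] * yb[None, :] * dB[s]
                    ).sum(axis=1)
                S = np.asarray(sigmoid_eval(pop, V))
                drift_y = pop.a_r * S * (1.0 - y) - pop.a_d * y
                diff_y = np.sqrt(np.abs(pop.a_r * S * (1.0 - y) + pop.a_d * y)) * np.asarray(
                    spec.chi(y)
                )
                y = y + drift_y * dt + diff_y * dWy[s]
                if pop.model_kind == "FHN":
                    f = pop.fhn
                    w = w + f.c * (V + f.a - f.b * w) * dt
                else:
                    for gi, gname in enumerate(("n", "m", "h")):
                        rho, zeta = pop.gates[gname].rates(gname, V)
                        x = gates[:, gi]
                        drift = rho * (1.0 - x) - zeta * x
                        diff = np.sqrt(np.abs(rho * (1.0 - x) + zeta * x)) * np.asarray(
                            spec.chi(x)
                        )
                        gates[:, gi] = x + drift * dt + diff * dWg[gname][s]
                if sign_preserving:
                    J = cir_step(J, theta[None, :], J_bar[None, :], sigma_J[None, :], dt, dB[s])
                V = V_new
                record(k + 1)
            done += nc

        V_T[lab] = V.copy()
        y_T[lab] = y.copy()
        if store_paths:
            V_paths[lab] = V_store
            y_paths[lab] = y_store

    return LimitEnsemble(
        t=grid, labels=labels, M=M,
        sbar_hat=sbar_hat, ybar_hat=ybar_hat, sbar_se_T=sbar_se_T,
        V_T=V_T, y_T=y_T, V_paths=V_paths, y_paths=y_paths,
    )


class PicardNonConvergence(RuntimeError):
    """Picard iteration failed to reach tolerance; carries the residuals."""

    def __init__(self, residuals):
        super().__init__(
            f"Picard iteration did not converge; residuals: {residuals}"
        )
        self.residuals = residuals


def picard_solve(
    spec: ModelSpec,
    init_law,
    T: float,
    dt: float,
    M: int = 2000,
    tol: float = 1e-3,
    max_iter: int = 25,
    seed=0,
    *,
    damping: float = 1.0,
) -> MeanFieldPaths:
    """Solve the mean-field fixed point by Monte-Carlo Picard iteration.

    Iterates (i) ybar^k from sbar^k in closed form, (ii) an M-copy limit
    ensemble driven by ybar^k under common random numbers (the same seed is
    reused each iteration, so the map is deterministic), (iii) sbar^{k+1}
    from the ensemble; stops when the sup-norm change of (sbar, ybar) falls
    below ``tol``.  The starting sbar^0 is the constant path E[S(V_0)]
    estimated from the initial law.  ``damping`` < 1 relaxes the sbar update
    for stiff configurations.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if init_law is None:
        from .presets import default_init_laws

        init_law = default_init_laws(spec)
    n_steps = _n_steps(T, dt)
    grid = np.arange(n_steps + 1) * dt
    labels = spec.labels
    p = spec.p_bar

    # initial-law functionals (held constant over t for the starting guess)
    from .model import sigmoid_eval

    y0_mean = np.empty(p)
    sbar = np.empty((p, n_steps + 1))
    for a, lab in enumerate(labels):
        draws = _pop_init_draws(spec, init_law, lab, M, seed)
        pop = spec.population(lab)
        sbar[a, :] = np.asarray(sigmoid_eval(pop, draws["V"])).mean()
        y0_mean[a] = draws["y"].mean()

    def ybar_of(sb):
        yb = np.empty_like(sb)
        for a, lab in enumerate(labels):
            pop = spec.population(lab)
            yb[a] = ybar_from_sbar(pop.a_r, pop.a_d, float(y0_mean[a]), sb[a], grid)
        return yb

    ybar = ybar_of(sbar)
    residuals: list[float] = []
    for it in range(1, max_iter + 1):
        paths = MeanFieldPaths(t=grid, labels=labels, sbar=sbar, ybar=ybar)
        ens = simulate_limit_ensemble(
            spec, paths, M, T, dt, seed, init_law=init_law
        )
        sbar_new = sbar + damping * (ens.sbar_hat - sbar)
        ybar_new = ybar_of(sbar_new)
        res = max(
            float(np.abs(sbar_new - sbar).max()), float(np.abs(ybar_new - ybar).max())
        )
        residuals.append(res)
        sbar, ybar = sbar_new, ybar_new
        if res < tol:
            return MeanFieldPaths(
                t=grid, labels=labels, sbar=sbar, ybar=ybar,
                iterations=it, residuals=residuals, sbar_se_T=ens.sbar_se_T,
            )
    raise PicardNonConvergence(residuals)
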