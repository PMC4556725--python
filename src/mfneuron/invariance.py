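"""Rectangular-cylinder invariance: boundary conditions and excursion statistics.

A proportion-valued coordinate of an SDE system stays in [0, 1] almost surely
when (i) its diffusion coefficient vanishes everywhere outside (0, 1) and
(ii) its drift points inward at the boundary — nonnegative on {x <= 0},
nonpositive on {x >= 1}.  The gating and synaptic coefficients of the neuron
models satisfy both by construction: the envelope chi kills the noise near
the boundary and the relaxation drift rho (1-x) - zeta x changes sign inside
(0, 1).

This module checks those two conditions numerically on grids that extend
beyond [0, 1] (to exercise the one-sided clauses, not just the boundary
points), and measures empirical containment: over an ensemble of simulated
paths, how many samples ever left [0, 1] and by how much.  The checks reduce
to one scalar constrained coordinate at a time, treating every other
coordinate as environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GATE_NAMES, ChiFunction, ModelSpec
from .network import NoiseStreams, Trajectory, _n_steps

__all__ = [
    "BoundaryFlags",
    "ExcursionStats",
    "check_scalar_coefficients",
    "check_boundary_conditions",
    "excursion_stats",
    "gate_sde_containment",
]


@dataclass(frozen=True)
class BoundaryFlags:
    """Verdict for one constrained coordinate: does the diffusion vanish
    outside (0, 1), and does the drift point inward at the boundary?
    ``first_violation`` records the first offending (x, v) grid point."""

    variable: str
    diffusion_vanishes_ok: bool
    drift_sign_ok: bool
    first_violation: tuple[float, float] | None = None

    @property
    def ok(self) -> bool:
        return self.diffusion_vanishes_ok and self.drift_sign_ok


def check_scalar_coefficients(drift_fn, diff_fn, x_grid, v_grid, name="x") -> BoundaryFlags:
    """Check one (drift, diffusion) pair on the product grid.

    ``drift_fn(v, x)`` and ``diff_fn(v, x)`` must broadcast over arrays.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    X = x_grid[None, :]
    V = v_grid[:, None]
    drift = np.broadcast_to(np.asarray(drift_fn(V, X), dtype=float), (v_grid.size, x_grid.size))
    diff = np.broadcast_to(np.asarray(diff_fn(V, X), dtype=float), (v_grid.size, x_grid.size))

    outside = (X <= 0.0) | (X >= 1.0)
    diff_bad = (diff != 0.0) & outside
    drift_bad = ((X <= 0.0) & (drift < 0.0)) | ((X >= 1.0) & (drift > 0.0))

    first = None
    for bad in (diff_bad, drift_bad):
        if bad.any() and first is None:
            iv, ix = np.argwhere(bad)[0]
            first = (float(x_grid[ix]), float(v_grid[iv]))
    return BoundaryFlags(
        variable=name,
        diffusion_vanishes_ok=not bool(diff_bad.any()),
        drift_sign_ok=not bool(drift_bad.any()),
        first_violation=first,
    )


def check_boundary_conditions(
    spec: ModelSpec,
    x_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
) -> list[BoundaryFlags]:
    """Boundary conditions for every gate and synapse coefficient pair of a spec.

    Default grids cover x in [-0.5, 1.5] and v in [-100, 100] mV, so the
    one-sided clauses are exercised away from the boundary as well.
    """
    if x_grid is None:
        x_grid = np.linspace(-0.5, 1.5, 201)
    if v_grid is None:
        v_grid = np.linspace(-100.0, 100.0, 101)
    from .model import gate_coefficients, synapse_coefficients

    flags: list[BoundaryFlags] = []
    for pop in spec.populations:
        def syn_drift(v, x, _p=pop):
            return synapse_coefficients(_p, spec.chi, v, x)[0]

        def syn_diff(v, x, _p=pop):
            return synapse_coefficients(_p, spec.chi, v, x)[1]

        flags.append(
            check_scalar_coefficients(
                syn_drift, syn_diff, x_grid, v_grid, name=f"{pop.label}:y"
            )
        )
        if pop.model_kind == "HH":
            for gname in GATE_NAMES:
                def g_drift(v, x, _p=pop, _g=gname):
                    return gate_coefficients(_p, spec.chi, _g, v, x)[0]

                def g_diff(v, x, _p=pop, _g=gname):
                    return gate_coefficients(_p, spec.chi, _g, v, x)[1]

                flags.append(
                    check_scalar_coefficients(
                        g_drift, g_diff, x_grid, v_grid, name=f"{pop.label}:{gname}"
                    )
                )
    return flags


@dataclass
class ExcursionStats:
    """Containment bookkeeping for proportion variables.

    ``max_distance`` is the largest distance of any sample from [0, 1];
    ``count_outside`` the number of offending samples; ``fraction_inside``
    the fraction of paths whose every sample stayed in [0, 1].
    """

    max_distance: float
    count_outside: int
    fraction_inside: float
    n_paths: int
    n_samples: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_inside <= 1.0:
            raise ValueError("fraction_inside must lie in [0, 1]")
        if (self.fraction_inside == 1.0) != (self.count_outside == 0):
            raise ValueError("fraction_inside == 1 iff count_outside == 0")


def _dist01(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.maximum(x - 1.0, -x), 0.0)


def excursion_stats(traj) -> ExcursionStats:
    """Exact containment counts over the *stored* samples of a trajectory or
    limit ensemble (pure bookkeeping; the data are not modified).

    For a network :class:`~mfneuron.network.Trajectory` the proportion
    variables are y and (for HH neurons) the gates, one path per neuron; for
    a :class:`~mfneuron.meanfield.LimitEnsemble` with stored paths, the y
    copies of every population.
    """
    if isinstance(traj, Trajectory):
        if traj.times.size == 0 or traj.V.size == 0:
            raise ValueError("empty trajectory")
        samples = [traj.y]  # (n_t, N)
        hh_cols = np.flatnonzero(np.abs(traj.gates).max(axis=(0, 2)) > 0)
        if hh_cols.size:
            samples.append(traj.gates[:, hh_cols, :].reshape(traj.times.size, -1))
        mats = np.concatenate(samples, axis=1)
    else:  # LimitEnsemble
        if getattr(traj, "y_paths", None) is None or not traj.y_paths:
            raise ValueError("ensemble has no stored paths; run with store_paths=True")
        mats = np.concatenate([traj.y_paths[lab] for lab in traj.labels], axis=1)
    d = _dist01(mats)
    outside = d > 0
    fully_inside = ~outside.any(axis=0)
    return ExcursionStats(
        max_distance=float(d.max()),
        count_outside=int(outside.sum()),
        fraction_inside=float(fully_inside.mean()),
        n_paths=int(mats.shape[1]),
        n_samples=int(mats.size),
    )


def gate_sde_containment(
    rho,
    zeta,
    chi: ChiFunction,
    x0: float,
    n_paths: int,
    T: float,
    dt: float,
    seed,
    *,
    clamp: bool = False,
) -> ExcursionStats:
    """Simulate the scalar gate SDE with frozen rates and count excursions.

        dx = (rho (1 - x) - zeta x) dt + sqrt(|rho (1 - x) + zeta x|) chi(x) dW

    ``rho`` and ``zeta`` are constants (1/ms).  Every Euler–Maruyama sample
    of every path is inspected online (nothing is clamped unless asked), so
    ``fraction_inside`` is exact over the full time grid.  This realizes the
    almost-sure containment statement empirically: with an envelope vanishing
    near the boundary and inward drift, no path should ever leave [0, 1].
    """
    n_steps = _n_steps(T, dt)
    noise = NoiseStreams(seed)
    ids = np.arange(n_paths)
    x = np.full(n_paths, float(x0))
    ever_out = np.zeros(n_paths, dtype=bool)
    count = 0
    max_d = float(_dist01(x).max())
    root = np.sqrt(dt)

    chunk = max(1, min(20_000, n_steps))
    done = 0
    while done < n_steps:
        nc = min(chunk, n_steps - done)
        dW = noise.block(ids, "gate", nc) * root
        for s in range(nc):
            drift = rho * (1.0 - x) - zeta * x
            diff = np.sqrt(np.abs(rho * (1.0 - x) + zeta * x)) * np.asarray(chi(x))
            x = x + drift * dt + diff * dW[s]
            if clamp:
                x = np.clip(x, 0.0, 1.0)
            d = _dist01(x)
            out = d > 0
            if out.any():
                ever_out |= out
                count += int(out.sum())
                max_d = max(max_d, float(d.max()))
        done += nc

    return ExcursionStats(
        max_distance=max_d,
        count_outside=count,
        fraction_inside=float(1.0 - ever_out.mean()),
        n_paths=n_paths,
        n_samples=n_paths * (n_steps + 1),
        provenance={"rho": float(rho), "zeta": float(zeta), "x0": float(x0),
                    "T": T, "dt": dt, "seed": repr(seed), "clamp": clamp},
    )
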