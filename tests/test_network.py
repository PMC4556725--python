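"""N-neuron particle-system simulation: stepping, noise streams, CIR scheme."""

import numpy as np
import pytest

import mfneuron as mf
from mfneuron.network import NoiseStreams, _n_steps, _sorted_mean
from mfneuron.presets import default_init_laws, fhn_one_population


class TestNoiseStreams:
    def test_reproducible_and_chunk_consistent(self):
        a = NoiseStreams(7).normals(3, "V", 100)
        ns = NoiseStreams(7)
        b = np.concatenate([ns.normals(3, "V", 60), ns.normals(3, "V", 40)])
        assert np.array_equal(a, b)

    def test_streams_mutually_independent_keys(self):
        ns = NoiseStreams(7)
        x = ns.normals(0, "V", 1000)
        y = ns.normals(1, "V", 1000)
        z = NoiseStreams(7).normals(0, "y", 1000)
        assert not np.array_equal(x, y)
        assert not np.array_equal(x, z)
        # distinct streams are uncorrelated
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.1


class TestPopulationSynapticInput:
    def test_constant_average(self, fhn_spec):
        layout = mf.PopulationLayout.from_proportions(fhn_spec, 8)
        state = mf.NetworkState(
            t=0.0, V=np.zeros(8), y=np.full(8, 0.5), w=np.zeros(8),
            gates=np.zeros((8, 3)), J=np.zeros((8, 1)),
        )
        assert mf.population_synaptic_input(state, layout, "exc") == 0.5

    def test_subpopulation_mean(self, fhn2_spec):
        layout = mf.PopulationLayout.from_proportions(fhn2_spec, 10)  # 8 exc, 2 inh
        y = np.zeros(10)
        inh = layout.members("inh")
        y[inh] = [0.2, 0.4]
        state = mf.NetworkState(
            t=0.0, V=np.zeros(10), y=y, w=np.zeros(10),
            gates=np.zeros((10, 3)), J=np.zeros((10, 2)),
        )
        assert mf.population_synaptic_input(state, layout, "inh") == pytest.approx(0.3)
        assert mf.population_synaptic_input(state, layout, "exc") == 0.0

    def test_unknown_label_errors(self, fhn_spec):
        layout = mf.PopulationLayout.from_proportions(fhn_spec, 4)
        state = mf.NetworkState(
            t=0.0, V=np.zeros(4), y=np.zeros(4), w=np.zeros(4),
            gates=np.zeros((4, 3)),
        )
        with pytest.raises(ValueError):
            mf.population_synaptic_input(state, layout, "nope")

    def test_sorted_mean_is_permutation_invariant(self, rng):
        v = rng.random(37)
        perm = rng.permutation(37)
        assert _sorted_mean(v) == _sorted_mean(v[perm])


class TestCIR:
    def test_fixed_point_without_noise(self):
        assert mf.cir_step(0.5, theta=1.3, J_bar=0.5, sigma_J=0.0, dt=0.01, z=1.0) == 0.5

    def test_zero_absorbing_with_zero_mean(self):
        for z in (-3.0, 0.0, 3.0):
            assert mf.cir_step(0.0, theta=1.0, J_bar=0.0, sigma_J=0.4, dt=0.01, z=z) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            mf.cir_step(-0.1, theta=1.0, J_bar=0.5, sigma_J=0.2, dt=0.01, z=0.0)

    def test_positivity_preserved(self, rng):
        J = rng.gamma(2.0, 0.25, 2000)
        dt = 1e-3
        for _ in range(200):
            z = rng.standard_normal(2000) * np.sqrt(dt)
            J = mf.cir_step(J, theta=1.0, J_bar=0.5, sigma_J=0.8, dt=dt, z=z)
        assert np.all(J >= 0)

    def test_mean_matches_closed_form(self, rng):
        """Monte-Carlo mean of the iterated scheme tracks
        J_bar + (J0 - J_bar) exp(-theta t) within 3 standard errors."""
        theta, J_bar, sigma, J0, dt = 1.0, 0.5, 0.3, 1.5, 1e-3
        n = 4000
        J = np.full(n, J0)
        t = 0.0
        for _ in range(1000):
            z = rng.standard_normal(n) * np.sqrt(dt)
            J = mf.cir_step(J, theta, J_bar, sigma, dt, z)
            t += dt
        exact = J_bar + (J0 - J_bar) * np.exp(-theta * t)
        se = J.std(ddof=1) / np.sqrt(n)
        assert abs(J.mean() - exact) < 3 * se + 1e-3 * dt  # tiny Euler bias allowance


class TestStepAndSimulate:
    def test_deterministic_fhn_matches_ode_euler(self):
        """With all noise and coupling off, one network step equals one
        explicit-Euler step of the deterministic FHN ODE (independent oracle)."""
        import dataclasses

        spec = dataclasses.replace(
            fhn_one_population(J_bar=0.0, sigma_J=0.0, sigma_V=0.0),
            chi=mf.ChiFunction(peak=0.0),
        )
        layout = mf.PopulationLayout.from_proportions(spec, 1)
        v0, w0, y0 = -1.0, 0.2, 0.4
        state = mf.NetworkState(
            t=0.0, V=np.array([v0]), y=np.array([y0]), w=np.array([w0]),
            gates=np.zeros((1, 3)), J=np.zeros((1, 1)),
        )
        dt = 1e-3
        nxt = mf.step_network(state, spec, layout, dt, NoiseStreams(0))
        # hand-coded explicit Euler of the ODE system
        p = spec.population("exc")
        S = 1.0 / (1.0 + np.exp(-v0))
        v1 = v0 + dt * (-(v0 ** 3) / 3 + v0 - w0)
        w1 = w0 + dt * p.fhn.c * (v0 + p.fhn.a - p.fhn.b * w0)
        y1 = y0 + dt * (p.a_r * S * (1 - y0) - p.a_d * y0)
        assert nxt.V[0] == pytest.approx(v1, rel=1e-14)
        assert nxt.w[0] == pytest.approx(w1, rel=1e-14)
        assert nxt.y[0] == pytest.approx(y1, rel=1e-14)

    def test_same_seed_bit_identical(self, fhn_spec, small_network):
        layout, init = small_network
        t1 = mf.simulate_network(fhn_spec, layout, init, T=1.0, dt=1e-3, seed=5)
        t2 = mf.simulate_network(fhn_spec, layout, init, T=1.0, dt=1e-3, seed=5)
        for name in ("V", "y", "w", "J"):
            assert np.array_equal(getattr(t1, name), getattr(t2, name))

    def test_no_randomness_identical_neurons(self):
        """Two uncoupled noise-free neurons from identical initial conditions
        follow the same deterministic path."""
        import dataclasses

        spec = dataclasses.replace(
            fhn_one_population(J_bar=0.0, sigma_J=0.0, sigma_V=0.0),
            chi=mf.ChiFunction(peak=0.0),
        )
        layout = mf.PopulationLayout.from_proportions(spec, 2)
        state = mf.NetworkState(
            t=0.0, V=np.array([-1.0, -1.0]), y=np.array([0.4, 0.4]),
            w=np.array([0.2, 0.2]), gates=np.zeros((2, 3)), J=np.zeros((2, 1)),
        )
        traj = mf.simulate_network(spec, layout, state, T=2.0, dt=1e-3, seed=0)
        assert np.array_equal(traj.V[:, 0], traj.V[:, 1])

    def test_exchangeability_bit_identical(self, fhn_spec, fhn_laws):
        """Permuting neurons within a population together with their noise
        stream ids permutes the output bit-identically."""
        layout = mf.PopulationLayout.from_proportions(fhn_spec, 8)
        init = mf.sample_initial_conditions(fhn_spec, fhn_laws, layout, seed=3)
        perm = np.array([5, 2, 7, 0, 4, 1, 6, 3])
        t_base = mf.simulate_network(fhn_spec, layout, init, T=0.5, dt=1e-3, seed=9)
        t_perm = mf.simulate_network(
            fhn_spec, layout.permuted(perm), init.permuted(perm),
            T=0.5, dt=1e-3, seed=9,
        )
        assert np.array_equal(t_perm.V, t_base.V[:, perm])
        assert np.array_equal(t_perm.y, t_base.y[:, perm])
        assert np.array_equal(t_perm.J, t_base.J[:, perm])

    def test_proportions_respected_and_incompatible_N_rejected(self, fhn2_spec):
        layout = mf.PopulationLayout.from_proportions(fhn2_spec, 10)
        assert layout.counts.tolist() == [8, 2]
        with pytest.raises(ValueError):
            mf.PopulationLayout.from_proportions(fhn2_spec, 7)

    def test_proportion_variables_contained(self, fhn_spec, fhn_laws):
        """All synaptic samples stay in [0, 1] at dt = 1e-4 without clamping
        (the boundary-preserving regime; coarser steps can overshoot the
        envelope support and are counted, not hidden)."""
        layout = mf.PopulationLayout.from_proportions(fhn_spec, 50)
        init = mf.sample_initial_conditions(fhn_spec, fhn_laws, layout, seed=21)
        traj = mf.simulate_network(
            fhn_spec, layout, init, T=2.0, dt=1e-4, seed=21, stride=10
        )
        assert traj.excursions["count"] == 0
        assert np.all((traj.y >= 0) & (traj.y <= 1))
        assert np.all(traj.J >= 0)

    def test_moment_stability_under_dt_halving(self, fhn_spec, fhn_laws):
        """max_t mean(V^2) is finite and stable when dt is halved."""
        layout = mf.PopulationLayout.from_proportions(fhn_spec, 30)
        init = mf.sample_initial_conditions(fhn_spec, fhn_laws, layout, seed=2)
        m = {}
        for dt in (1e-3, 5e-4):
            traj = mf.simulate_network(fhn_spec, layout, init, T=2.0, dt=dt, seed=2)
            m[dt] = float((traj.V ** 2).mean(axis=1).max())
        assert np.isfinite(m[1e-3]) and np.isfinite(m[5e-4])
        assert m[1e-3] == pytest.approx(m[5e-4], rel=0.25)

    def test_strong_dt_convergence_with_shared_noise(self, fhn_spec, fhn_laws):
        """Strong error of V against a dt/4 reference decreases at order
        ~0.5-1.0 under dt halving (Euler–Maruyama regime), with shared noise."""
        from mfneuron.network import _SimContext, _step

        layout = mf.PopulationLayout.from_proportions(fhn_spec, 10)
        init = mf.sample_initial_conditions(fhn_spec, fhn_laws, layout, seed=4)
        ctx = _SimContext(fhn_spec, layout)
        dt_f = 2.5e-4
        n_f = 2000  # T = 0.5 ms at the fine step
        rng = np.random.default_rng(4)
        fine = {
            "V": rng.standard_normal((n_f, 10)) * np.sqrt(dt_f),
            "y": rng.standard_normal((n_f, 10)) * np.sqrt(dt_f),
            "B": rng.standard_normal((n_f, 10, 1)) * np.sqrt(dt_f),
        }

        def run(level):  # level 0: dt_f; 1: 2*dt_f; 2: 4*dt_f
            k = 2 ** level
            dt = dt_f * k
            st = init.copy()
            for s in range(n_f // k):
                dW = {c: a[s * k:(s + 1) * k].sum(axis=0) for c, a in fine.items()}
                st = _step(ctx, st, dt, dW)
            return st.V

        ref = run(0)
        e1 = np.sqrt(((run(1) - ref) ** 2).mean())
        e2 = np.sqrt(((run(2) - ref) ** 2).mean())
        order = np.log2(e2 / e1)
        assert 0.3 < order < 1.5

    def test_non_integer_step_count_rejected(self, fhn_spec, small_network):
        layout, init = small_network
        with pytest.raises(ValueError):
            mf.simulate_network(fhn_spec, layout, init, T=1.0005, dt=1e-3, seed=0)
        assert _n_steps(1.0, 1e-3) == 1000

    def test_trajectory_hdf5_roundtrip(self, fhn_spec, small_network, tmp_path):
        layout, init = small_network
        traj = mf.simulate_network(fhn_spec, layout, init, T=0.1, dt=1e-3, seed=1)
        path = tmp_path / "traj.h5"
        traj.to_hdf5(path)
        back = mf.Trajectory.from_hdf5(path)
        assert np.array_equal(back.V, traj.V)
        assert np.array_equal(back.J, traj.J)
        assert back.excursions["count"] == traj.excursions["count"]
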