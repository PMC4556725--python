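"""Coefficient functions and hypothesis validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mfneuron as mf
from mfneuron.model import GateKinetics, SigmoidParams, hh_rate


def pop_with_sigmoid(C, lam, delta):
    return mf.PopulationSpec(label="p", sigmoid=SigmoidParams(C=C, lam=lam, delta=delta))


class TestSigmoid:
    @pytest.mark.parametrize(
        "C, lam, delta, v, expected",
        [
            (1.0, 1.0, 0.0, 0.0, 0.5),                      # S(delta) = C/2
            (2.0, 0.5, 1.0, 3.0, 2.0 / (1.0 + np.exp(-1.0))),
            (1.0, 1.0, 0.0, -700.0, 0.0),                   # lower asymptote
        ],
    )
    def test_values(self, C, lam, delta, v, expected):
        s = mf.sigmoid_eval(pop_with_sigmoid(C, lam, delta), v)
        assert s == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @settings(deadline=None, max_examples=50)
    @given(
        C=st.floats(0.1, 10),
        lam=st.floats(0.01, 5),
        delta=st.floats(-50, 50),
    )
    def test_monotone_and_bounded(self, C, lam, delta):
        pop = pop_with_sigmoid(C, lam, delta)
        v = np.linspace(delta - 10 / lam, delta + 10 / lam, 201)
        s = mf.sigmoid_eval(pop, v)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < C))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(C=-1.0)
        with pytest.raises(ValueError):
            SigmoidParams(lam=0.0)


class TestChi:
    def test_vanishes_outside_support(self):
        chi = mf.ChiFunction()
        for x in (0.0, 1.0, -0.3, 1.2, 0.05, 0.95):
            assert mf.chi_eval(chi, x) == 0.0

    def test_trapezoid_plateau_and_ramps(self):
        chi = mf.ChiFunction(lo=0.05, hi=0.95, peak=1.0, ramp=0.05)
        assert mf.chi_eval(chi, 0.5) == 1.0
        assert mf.chi_eval(chi, 0.1) == pytest.approx(1.0)
        assert mf.chi_eval(chi, 0.075) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30)
    @given(x=st.floats(-1, 2), y=st.floats(-1, 2),
           shape=st.sampled_from(["trapezoid", "cosine_bump"]))
    def test_lipschitz_and_peak_bound(self, x, y, shape):
        chi = mf.ChiFunction(shape=shape)
        cx, cy = float(np.asarray(chi(x))), float(np.asarray(chi(y)))
        assert 0.0 <= cx <= chi.peak
        assert abs(cx - cy) <= chi.lipschitz_constant * abs(x - y) + 1e-12

    def test_invalid_support_rejected(self):
        with pytest.raises(ValueError):
            mf.ChiFunction(lo=0.0, hi=0.95)
        with pytest.raises(ValueError):
            mf.ChiFunction(lo=0.5, hi=0.4)


class TestFHNDrift:
    @pytest.mark.parametrize(
        "v, w, expected",
        [(0.0, 0.0, 0.0), (1.0, 0.0, 2.0 / 3.0), (2.0, 5.0, -17.0 / 3.0)],
    )
    def test_values(self, v, w, expected):
        pop = mf.PopulationSpec(label="p", model_kind="FHN")
        assert mf.fhn_drift(pop, v, w) == pytest.approx(expected, rel=1e-15)


class TestHHMembraneDrift:
    def _pop(self, **kw):
        return mf.PopulationSpec(
            label="h", model_kind="HH", hh_drift_params=mf.HHDriftParams(**kw)
        )

    def test_leak_free_limit_returns_applied_current(self):
        pop = self._pop(g_na=0.0, g_k=0.0, g_l=0.0, i_app=7.5)
        assert mf.hh_membrane_drift(pop, -65.0, 0.3, 0.1, 0.6) == 7.5

    def test_leak_equilibrium(self):
        pop = self._pop(g_na=0.0, g_k=0.0, g_l=0.3, e_l=-54.387, i_app=0.0)
        assert mf.hh_membrane_drift(pop, -54.387, 0.0, 0.0, 0.0) == 0.0

    def test_against_independent_evaluation(self):
        # independent hand-coded oracle of the classic HH membrane equation
        g_na, e_na, g_k, e_k, g_l, e_l = 120.0, 50.0, 36.0, -77.0, 0.3, -54.387
        v, n, m, h = -65.0, 0.3177, 0.0529, 0.5961
        expected = -(
            g_na * m * m * m * h * (v - e_na)
            + g_k * n * n * n * n * (v - e_k)
            + g_l * (v - e_l)
        )
        pop = self._pop()
        assert mf.hh_membrane_drift(pop, v, n, m, h) == pytest.approx(expected, rel=1e-14)


class TestLangevinCoefficients:
    def _pop_const_rates(self, rho, zeta):
        gates = {
            g: GateKinetics(kind="constant", rho_const=rho, zeta_const=zeta)
            for g in ("n", "m", "h")
        }
        return mf.PopulationSpec(label="h", model_kind="HH", gates=gates)

    @pytest.mark.parametrize(
        "rho, zeta, x, drift, diff",
        [
            (0.5, 0.3, 0.0, 0.5, 0.0),
            (0.5, 0.3, 1.0, -0.3, 0.0),
            (0.5, 0.5, 0.5, 0.0, np.sqrt(0.5)),
        ],
    )
    def test_gate_values(self, rho, zeta, x, drift, diff):
        pop = self._pop_const_rates(rho, zeta)
        chi = mf.ChiFunction()
        d, s = mf.gate_coefficients(pop, chi, "n", 0.0, x)
        assert d == pytest.approx(drift, rel=1e-14)
        assert s == pytest.approx(diff, rel=1e-14)

    def test_synapse_values(self):
        # a_r = a_d = 1, S(0) = 0.5 for the default sigmoid, chi(0.25) = 1
        pop = mf.PopulationSpec(label="p", a_r=1.0, a_d=1.0)
        chi = mf.ChiFunction()
        d, s = mf.synapse_coefficients(pop, chi, 0.0, 0.25)
        assert d == pytest.approx(0.125, rel=1e-14)
        assert s == pytest.approx(np.sqrt(0.625), rel=1e-14)
        d0, s0 = mf.synapse_coefficients(pop, chi, 0.0, 0.0)
        assert d0 > 0 and s0 == 0.0
        d1, s1 = mf.synapse_coefficients(pop, chi, 0.0, 1.0)
        assert d1 == -pop.a_d and s1 == 0.0

    @settings(deadline=None, max_examples=40)
    @given(v=st.floats(-100, 100), x=st.floats(-0.5, 1.5))
    def test_boundary_signs_and_vanishing(self, v, x):
        """Diffusion vanishes outside (0,1); drift points inward at the
        boundary, for gates and synapse alike."""
        pop = self._pop_const_rates(0.7, 0.4)
        chi = mf.ChiFunction()
        for d, s in (
            mf.gate_coefficients(pop, chi, "m", v, x),
            mf.synapse_coefficients(pop, chi, v, x),
        ):
            if x <= 0.0 or x >= 1.0:
                assert s == 0.0
            if x <= 0.0:
                assert d >= 0.0
            if x >= 1.0:
                assert d <= 0.0

    def test_sqrt_argument_coercive_on_unit_interval(self):
        """rho(1-x) + zeta x >= nu > 0 for x in [0,1] under the rate floor."""
        pop = mf.presets.hh_one_population().population("hh")
        v = np.linspace(-100, 100, 101)[:, None]
        x = np.linspace(0.0, 1.0, 101)[None, :]
        for g in ("n", "m", "h"):
            rho, zeta = pop.gates[g].rates(g, v)
            arg = rho * (1 - x) + zeta * x
            assert arg.min() >= pop.gates[g].nu


class TestOneSidedLipschitz:
    def test_fhn_constant_is_exactly_one(self):
        grid = np.arange(-300, 301) / 100.0
        L = mf.estimate_one_sided_lipschitz(
            lambda v, q: -(v ** 3) / 3.0 + v - q,
            lambda v, vp: (np.abs(v) - np.abs(vp)) ** 2 / 3.0,
            grid,
        )
        assert L == 1.0

    def test_linear_drift(self):
        grid = np.linspace(-2, 2, 81)
        k = 2.0
        L = mf.estimate_one_sided_lipschitz(lambda v, q: -k * v, None, grid)
        assert L == pytest.approx(-k, abs=1e-15)

    def test_constant_drift_gives_zero(self):
        grid = np.linspace(-1, 1, 21)
        assert mf.estimate_one_sided_lipschitz(lambda v, q: 3.0 + 0.0 * v, None, grid) == 0.0

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            mf.estimate_one_sided_lipschitz(lambda v, q: v, None, np.array([]))


class TestValidateHypotheses:
    def test_default_fhn_passes(self, fhn_spec):
        rep = mf.validate_hypotheses(fhn_spec)
        assert rep.ok
        assert rep.one_sided_L["exc"] == 1.0

    def test_default_hh_passes(self, hh_spec):
        rep = mf.validate_hypotheses(hh_spec)
        assert rep.ok
        assert rep.nu_hat is not None and rep.nu_hat > 0

    def test_flat_chi_fails(self, fhn_spec):
        class FlatChi:
            peak = 1.0
            lipschitz_constant = 0.0

            def __call__(self, x):
                return np.ones_like(np.asarray(x, dtype=float))

        import dataclasses

        spec = dataclasses.replace(fhn_spec, chi=FlatChi())
        rep = mf.validate_hypotheses(spec)
        assert not rep.chi_ok
        assert not rep.ok

    def test_vanishing_rate_fails_coercivity(self):
        gates = {
            g: GateKinetics(kind="custom", nu=1e-12,
                            rho_fn=lambda v: np.full_like(v, 0.5),
                            zeta_fn=lambda v: np.zeros_like(v))
            for g in ("n", "m", "h")
        }
        pop = mf.PopulationSpec(label="h", model_kind="HH", gates=gates)
        spec = mf.ModelSpec(
            populations=(pop,),
            interactions={("h", "h"): mf.InteractionSpec(theta=1.0)},
        )
        rep = mf.validate_hypotheses(spec)
        assert not rep.rates_ok
        assert rep.nu_hat == 0.0
        assert not rep.ok

    def test_report_serializes(self, fhn_spec):
        import json

        doc = json.loads(mf.validate_hypotheses(fhn_spec).to_json())
        assert doc["ok"] is True


class TestModelSpecInvariants:
    def test_state_dimension(self, fhn_spec, fhn2_spec):
        assert fhn_spec.state_dim == 1 + 6
        assert fhn2_spec.state_dim == 4 + 12

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mf.ModelSpec(
                populations=(mf.PopulationSpec(label="a"),),
                interactions={},
                proportions={"a": 0.7},
            )

    def test_theta_rejected_in_simple_model(self):
        with pytest.raises(ValueError):
            mf.InteractionSpec(conductance_model="simple", theta=1.0)

    def test_theta_required_in_sign_preserving(self):
        with pytest.raises(ValueError):
            mf.InteractionSpec(conductance_model="sign_preserving", theta=None)

    def test_unknown_population_in_interactions(self):
        with pytest.raises(ValueError):
            mf.ModelSpec(
                populations=(mf.PopulationSpec(label="a"),),
                interactions={("a", "zz"): mf.InteractionSpec(theta=1.0)},
            )

    def test_hh_rate_bounds(self):
        v = np.linspace(-200, 200, 401)  # beyond the clip, on purpose
        for g in ("n", "m", "h"):
            for which in ("rho", "zeta"):
                r = hh_rate(g, which, v)
                assert np.all(r >= 0) and np.all(r <= 30.0)
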