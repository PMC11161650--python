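import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endonet import (
    DynamicsParams,
    SystemState,
    eta_rhs,
    integrate_to_steady,
    network_from_edges,
    production_rate,
    rhs,
)
from oracles import rk4_integrate, spec_to_sets

CYCLIN_NET = network_from_edges(
    [
        ("Myc", "CyclinE/Cdk2", 1),
        ("E2F", "CyclinE/Cdk2", 1),
        ("p21", "CyclinE/Cdk2", -1),
        ("p27", "CyclinE/Cdk2", -1),
        ("PTEN", "CyclinE/Cdk2", -1),
        # keep regulators live so the spec has no floating inputs in tests
        ("Myc", "Myc", 1),
    ]
)


class TestProductionRate:
    def test_no_activators_means_zero_production(self):
        spec = network_from_edges([("A", "B", -1), ("B", "B", 1)])
        assert production_rate({"A": 1.0, "B": 0.7}, "A", spec) == 0.0

    def test_single_activator_at_one(self):
        spec = network_from_edges([("A", "B", 1)])
        # 10*1 / (1 + 10*1) = 10/11
        assert production_rate({"A": 1.0}, "B", spec) == pytest.approx(10 / 11, abs=1e-12)

    def test_activator_and_inhibitor_at_one(self):
        spec = network_from_edges([("A", "C", 1), ("B", "C", -1)])
        # (10/11) * (1/11)
        got = production_rate({"A": 1.0, "B": 1.0}, "C", spec)
        assert got == pytest.approx(10 / 121, abs=1e-12)

    def test_unknown_target_raises(self):
        spec = network_from_edges([("A", "B", 1)])
        with pytest.raises(KeyError):
            production_rate({"A": 1.0}, "Z", spec)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        xa=st.floats(0.0, 5.0),
        xb=st.floats(0.0, 5.0),
        bump=st.floats(1e-6, 1.0),
    )
    def test_bounded_and_monotone(self, xa, xb, bump):
        """g in [0,1), nondecreasing in activators, nonincreasing in inhibitors."""
        spec = network_from_edges([("A", "C", 1), ("B", "C", -1)])
        g = production_rate({"A": xa, "B": xb}, "C", spec)
        assert 0.0 <= g < 1.0
        g_up_act = production_rate({"A": xa + bump, "B": xb}, "C", spec)
        g_up_inh = production_rate({"A": xa, "B": xb + bump}, "C", spec)
        assert g_up_act >= g
        assert g_up_inh <= g


class TestEtaRhs:
    def test_zero_velocity_freezes_eta(self):
        assert eta_rhs(0.0, 1.3, 0.8) == 0.0

    def test_positive_velocity_raises_eta(self):
        # 1.5 * (0.01 + 2*0.1*1*0.5) = 0.165
        assert eta_rhs(0.1, 1.0, 0.5) == pytest.approx(0.165, abs=1e-12)

    def test_negative_velocity_lowers_eta(self):
        # 1.5 * (0.01 - 2*0.1*1*0.5) = -0.135
        assert eta_rhs(-0.1, 1.0, 0.5) == pytest.approx(-0.135, abs=1e-12)


class TestRhs:
    def test_cyclin_node_equation(self):
        """dx/dt of Cyclin E/Cdk2 with Myc=E2F=1, inhibitors 0, x=0, eta=1."""
        spec = CYCLIN_NET
        n = spec.n_nodes
        x = np.zeros(n)
        x[spec.index("Myc")] = 1.0
        x[spec.index("E2F")] = 1.0
        state = SystemState(x, np.ones(n))
        d = rhs(state, spec)
        # (10*(1+1)) / (1 + 10*(1+1)) = 20/21
        assert d.x[spec.index("CyclinE/Cdk2")] == pytest.approx(20 / 21, abs=1e-12)

    def test_clamped_node_derivatives_are_exactly_zero(self, toggle):
        state = SystemState(np.array([0.9, 0.4]), np.array([1.0, 1.0]))
        d = rhs(state, toggle, clamps={"A": 0.9})
        i = toggle.index("A")
        assert d.x[i] == 0.0
        assert d.eta[i] == 0.0
        assert d.x[1 - i] != 0.0

    def test_clamp_on_unknown_node_raises(self, toggle):
        state = SystemState(np.zeros(2), np.ones(2))
        with pytest.raises(KeyError):
            rhs(state, toggle, clamps={"Z": 1.0})

    def test_derivatives_vanish_at_converged_state(self, toggle, fixed_eta_params):
        out = integrate_to_steady(
            SystemState(np.array([0.9, 0.1]), np.ones(2)), toggle, fixed_eta_params
        )
        assert out.status == "converged"
        d = rhs(out.state, toggle, fixed_eta_params)
        assert np.max(np.abs(d.x)) < fixed_eta_params.steady_tol


class TestIntegrateToSteady:
    def test_toggle_converges_to_oracle_state(self, toggle, fixed_eta_params):
        """From (0.9, 0.1) the trajectory lands on the high/low state found
        by the independent RK4 oracle."""
        out = integrate_to_steady(
            SystemState(np.array([0.9, 0.1]), np.ones(2)), toggle, fixed_eta_params
        )
        assert out.status == "converged"
        acts, inhs = spec_to_sets(toggle)
        oracle = rk4_integrate(np.array([0.9, 0.1]), acts, inhs, eta=1.0)[0]
        assert np.max(np.abs(out.state.x - oracle)) < 1e-6
        assert out.state.x[0] > 0.8 and out.state.x[1] < 1e-3

    def test_repressilator_is_oscillatory(self, repressilator, osc_params):
        rng = np.random.default_rng(5)
        x0 = rng.uniform(0.3, 1.0, size=4)
        out = integrate_to_steady(
            SystemState(x0, np.ones(4)), repressilator, osc_params
        )
        assert out.status == "oscillatory"
        assert out.amplitude is not None
        ring = [repressilator.index(n) for n in ("R1", "R2", "R3")]
        assert np.all(out.amplitude[ring] > 0.05)

    def test_clamped_node_holds_exact_value_at_termination(self, toggle):
        out = integrate_to_steady(
            SystemState(np.array([0.3, 0.6]), np.ones(2)),
            toggle,
            DynamicsParams(),
            clamps={"B": 1.0},
        )
        assert out.state.x[toggle.index("B")] == 1.0

    def test_eta_stays_at_or_above_floor(self, toggle):
        """Downward transients drive eta negative in the raw law; the
        integrator clips at the floor."""
        params = DynamicsParams(eta_floor=1e-3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            state0 = SystemState(rng.uniform(0, 1, 2), rng.uniform(0.5, 1.5, 2))
            out = integrate_to_steady(state0, toggle, params)
            assert np.all(out.state.eta >= params.eta_floor - 1e-15)

    def test_eta_disabled_reduces_to_classical_form(self, toggle, fixed_eta_params):
        state = SystemState(np.array([0.4, 0.7]), np.array([0.6, 1.4]))
        d = rhs(state, toggle, fixed_eta_params)
        g0 = production_rate(state.x, "A", toggle, fixed_eta_params)
        assert d.x[toggle.index("A")] == pytest.approx(g0 - 1.0 * 0.4, abs=1e-12)
        assert np.all(d.eta == 0.0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"hill_n": 0.5},
            {"hill_a": 0.0},
            {"eta_floor": 0.0},
            {"steady_tol": 0.0},
            {"window": 600.0},
        ],
    )
    def test_bad_params_rejected(self, kw):
        with pytest.raises(ValueError):
            DynamicsParams(**kw)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            SystemState(np.array([1.0, np.nan]), np.ones(2))
        with pytest.raises(ValueError):
            SystemState(np.ones(3), np.ones(2))
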