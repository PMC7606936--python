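import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurovuln import (
    CellMolecularState,
    InvalidParameterError,
    ConfigurationError,
    NetworkParameters,
    NodeActivities,
    ScenarioConfig,
    apply_scenario,
    basal_state,
    hill,
    node_rates,
    scenario_config,
)
from neurovuln.network import NODES, network_edges, state_rates, relaxation_times

from conftest import no_stress_params


class TestHill:
    @pytest.mark.parametrize(
        "x,K,n,mode,expected",
        [
            (0.5, 0.5, 2, "activation", 0.5),      # half-saturation by construction
            (0.0, 0.5, 2, "activation", 0.0),
            (0.0, 0.5, 2, "repression", 1.0),
            (1.5, 0.5, 4, "activation", 81.0 / 82.0),  # x = 3K, n = 4
        ],
    )
    def test_values(self, x, K, n, mode, expected):
        assert hill(x, K, n, mode) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("K,n", [(0.0, 2), (-1.0, 2), (0.5, 0.5)])
    def test_invalid_parameters(self, K, n):
        with pytest.raises(InvalidParameterError):
            hill(1.0, K, n)

    def test_unknown_mode(self):
        with pytest.raises(InvalidParameterError):
            hill(1.0, 1.0, 2, "sigmoid")

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(0, 50, allow_nan=False),
        K=st.floats(0.01, 10),
        n=st.floats(1, 8),
    )
    def test_activation_repression_sum_to_one(self, x, K, n):
        a = hill(x, K, n, "activation")
        r = hill(x, K, n, "repression")
        assert 0.0 <= a <= 1.0 and 0.0 <= r <= 1.0
        assert a + r == pytest.approx(1.0, abs=1e-9)


class TestNodeRates:
    def test_zero_at_unstressed_fixed_point(self):
        p = no_stress_params()
        state = basal_state(p, tol=1e-13)
        rates = node_rates(state, p, damaged_fraction=0.0)
        assert np.all(np.abs(rates) < 1e-9)

    def test_tau_accumulates_under_high_ros_without_clearance(self, params):
        p = dataclasses.replace(
            params,
            tau_clearance_basal=0.0,
            tau_clearance_weight_bec1=0.0,
            tau_clearance_weight_uprer=0.0,
        )
        state = CellMolecularState(
            ros=10.0 * p.tau_ros_K, tau=1.0, activities=basal_state(p).activities
        )
        rates = node_rates(state, p, 0.0)
        assert rates[1] > 0  # d(tau)/dt

    def test_skn1_loss_raises_ros_derivative(self, params):
        state = basal_state(params)
        state.ros = 1.0
        ko = apply_scenario(params, scenario_config("skn1-ablation"))
        ko = dataclasses.replace(ko, skn1_expression_scale=0.0)
        # push skn-1 activity to its scenario level before comparing
        act_hi = state.activities.as_array()
        act_lo = act_hi.copy()
        act_lo[NODES.index("skn1")] = 0.0
        s_hi = CellMolecularState(1.0, 0.2, NodeActivities.from_array(act_hi))
        s_lo = CellMolecularState(1.0, 0.2, NodeActivities.from_array(act_lo))
        assert node_rates(s_lo, ko, 0.1)[0] > node_rates(s_hi, params, 0.1)[0]

    def test_deterministic_bitwise(self, params):
        state = basal_state(params)
        r1 = node_rates(state, params, 0.3)
        r2 = node_rates(state, params, 0.3)
        assert np.array_equal(r1, r2)

    def test_rates_finite_across_random_parameter_draws(self, params):
        from neurovuln import sample_agent_params

        rng = np.random.default_rng(7)
        for _ in range(25):
            p = sample_agent_params(params, 0.2, rng)
            A = np.clip(rng.random(len(NODES)), 0, 1)
            dR, dT, dA = state_rates(
                float(rng.random() * 3), float(rng.random() * 3), A,
                float(rng.random() * 20), float(rng.random()), p,
            )
            assert np.all(np.isfinite([dR, dT])) and np.all(np.isfinite(dA))


class TestActivityBounds:
    def test_activities_confined_to_unit_interval(self, params):
        """Integrated activities never leave [0,1], any start, random draws."""
        from neurovuln import sample_agent_params

        rng = np.random.default_rng(3)
        for trial in range(10):
            p = sample_agent_params(params, 0.25, rng)
            A = rng.random(len(NODES))
            relax = relaxation_times(p, like=A)
            R, T = 2.0 * rng.random(), 2.0 * rng.random()
            for step in range(400):
                _, _, dA = state_rates(R, T, A, step * 0.01, 0.2, p)
                A = A + 0.01 * dA
                assert np.all(A >= -1e-9) and np.all(A <= 1 + 1e-9)

    def test_basal_fixed_point_is_stable(self):
        """Perturbations of +-0.05 relax back within 5 simulated days."""
        p = no_stress_params()
        ref = basal_state(p, tol=1e-13)
        A0 = ref.activities.as_array()
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = np.clip(A0 + rng.uniform(-0.05, 0.05, size=len(NODES)), 0, 1)
            R, T = max(ref.ros + rng.uniform(-0.05, 0.05), 0), max(
                ref.tau + rng.uniform(-0.05, 0.05), 0
            )
            dt = 0.01
            for step in range(int(5 / dt)):
                dR, dT, dA = state_rates(R, T, A, 0.0, 0.0, p)
                R, T = max(R + dt * dR, 0), max(T + dt * dT, 0)
                A = np.clip(A + dt * dA, 0, 1)
            assert np.max(np.abs(A - A0)) < 5e-3
            assert abs(R - ref.ros) < 5e-3 and abs(T - ref.tau) < 5e-3


class TestScenarios:
    def test_identity_scenario_preserves_parameters(self, params):
        cfg = ScenarioConfig(scenario_name="normal")
        assert apply_scenario(params, cfg) == params

    def test_tau_scenario_doubles_aggregation(self, params):
        eff = apply_scenario(params, scenario_config("tau"))
        assert eff.tau_scenario_multiplier == 2.0

    def test_skn1_ablation_and_overexpression(self, params):
        lo = apply_scenario(params, scenario_config("skn1-ablation"))
        hi = apply_scenario(params, scenario_config("skn1-oe"))
        assert lo.skn1_expression_scale == pytest.approx(0.10)
        assert hi.skn1_expression_scale == pytest.approx(1.50)

    def test_base_left_unmodified(self, params):
        before = params.to_dict()
        apply_scenario(params, scenario_config("tau-uprer-deficient"))
        assert params.to_dict() == before

    def test_unknown_node_rejected(self, params):
        cfg = ScenarioConfig(node_scales={"skn1": 0.5})
        cfg.node_scales["sknX"] = 0.5  # bypass construction-time validation
        with pytest.raises(ConfigurationError):
            apply_scenario(params, cfg)

    def test_unknown_scenario_name(self):
        with pytest.raises(ConfigurationError):
            scenario_config("immortality")


class TestValidation:
    def test_negative_rate_rejected(self, params):
        bad = dataclasses.replace(params, death_hazard=-1.0)
        with pytest.raises(InvalidParameterError):
            bad.validate()

    def test_hub_self_feedback_needs_cooperativity(self, params):
        bad = dataclasses.replace(params, uprmt_self_n=1.0)
        with pytest.raises(InvalidParameterError):
            bad.validate()

    def test_activity_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            NodeActivities(uprmt_hsp60=1.2).validate()

    def test_config_dt_bounds(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(dt=0.5).validate()


def test_edge_list_covers_signature_nodes(params):
    edges = network_edges(params)
    targets = {e["target"] for e in edges}
    for node in ("uprmt_hsp60", "uprer_bip", "sod2", "bec1", "pink1", "tau", "ros"):
        assert node in targets
    assert all(e["sign"] in "+-" for e in edges)
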