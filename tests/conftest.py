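import dataclasses

import numpy as np
import pytest

from neurovuln import NetworkParameters, ScenarioConfig
from neurovuln.engine import run_simulation


@pytest.fixture(scope="session")
def params():
    return NetworkParameters()


@pytest.fixture(scope="session")
def small_normal_traj():
    """One small default normal-aging run shared across tests."""
    cfg = ScenarioConfig(n_cells=60, duration=20.0, dt=0.02, seed=42)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def small_tau_traj():
    from neurovuln import scenario_config

    cfg = scenario_config("tau", n_cells=60, duration=20.0, dt=0.02, seed=42)
    return run_simulation(cfg)


def no_stress_params() -> NetworkParameters:
    """All stressor production channels silenced."""
    return dataclasses.replace(
        NetworkParameters(),
        ros_basal_production=0.0,
        ros_age_production=0.0,
        tau_production_basal=0.0,
        mito_damage_rate=0.0,
        mito_tau_damage_rate=0.0,
    )
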