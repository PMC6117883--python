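import numpy as np
import pytest

from tundraflux.design import (
    DesignConfig,
    SimulationConfig,
    build_design,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_design():
    return build_design(DesignConfig())


@pytest.fixture(scope="session")
def quiet_sim(default_design):
    """A zero-noise synthetic experiment: every stage should recover truth exactly."""
    from dataclasses import replace

    truth = {g: replace(t, residual_sd=0.0)
             for g, t in SimulationConfig().calibration_truth.items()}
    cfg = SimulationConfig(seed=7, chamber_noise_sd=0.0, calibration_truth=truth)
    return simulate_experiment(cfg, default_design)


@pytest.fixture(scope="session")
def noisy_sim(default_design):
    """A realistic synthetic experiment at the default noise levels."""
    return simulate_experiment(SimulationConfig(seed=11), default_design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
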