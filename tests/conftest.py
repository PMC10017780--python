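import numpy as np
import pytest

from revlearn import AgentParams, generate_schedule, simulate_agent


@pytest.fixture(scope="session")
def default_params():
    return AgentParams()


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(2, 160, seed=7)


@pytest.fixture(scope="session")
def session_mu3(default_params, schedule):
    """One simulated session under the volatility-coupled response model."""
    trials, traj = simulate_agent(default_params, schedule, "hgf3_mu3", seed=11)
    return trials, traj


@pytest.fixture(scope="session")
def ten_trial_u():
    return np.array([1, 1, 0, 1, 0, 0, 1, 1, 1, 0], dtype=float)
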