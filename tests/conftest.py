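from __future__ import annotations

import numpy as np
import pytest

from pk_agents import AgentState, SimulationConfig, Trajectory
from pk_agents.dynamics import step


@pytest.fixture
def single_cfg() -> SimulationConfig:
    return SimulationConfig(n_agents=1, p=(10.0,), n_steps=100, seed=42)


@pytest.fixture
def two_agent_cfg() -> SimulationConfig:
    return SimulationConfig(n_agents=2, p=(10.0, 50.0), social_enabled=True,
                            env_enabled=True, alpha=0.5, beta=0.5,
                            n_steps=100, seed=7)


def run_from(states: list[AgentState], config: SimulationConfig,
             seed: int = 0) -> Trajectory:
    """Roll a trajectory forward from explicit initial states via step()."""
    rng = np.random.default_rng(seed)
    n = len(states)
    positions = np.empty((config.n_steps + 1, n, 2))
    headings = np.empty((config.n_steps + 1, n))
    positions[0] = [s.position for s in states]
    headings[0] = [s.heading for s in states]
    for t in range(config.n_steps):
        states = step(states, config, rng)
        positions[t + 1] = [s.position for s in states]
        headings[t + 1] = [s.heading for s in states]
    return Trajectory(positions=positions, headings=headings, config=config)
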