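"""Shared fixtures: desk-scale configurations and one reusable motor run.

All simulations in the suite use the 100-neuron-pool test profile; recurrent
weights are size-rescaled so pool dynamics match the full 500-neuron model.
"""

import pytest

import chainsim as cs
from chainsim.config import ChainSpec


@pytest.fixture()
def tcfg():
    """Fresh desk-scale config (100-neuron pools, two chains)."""
    return cs.test_profile_config(seed=1)


@pytest.fixture()
def single_chain_cfg():
    """Desk-scale config with only the eat chain (faster simulations)."""
    cfg = cs.test_profile_config(seed=1)
    cfg.network.chains = [
        ChainSpec("eat", ["reaching", "shaping", "grasping", "bringing_to_mouth"])]
    return cfg


def _single_chain_cfg(seed=1):
    cfg = cs.test_profile_config(seed=seed)
    cfg.network.chains = [
        ChainSpec("eat", ["reaching", "shaping", "grasping", "bringing_to_mouth"])]
    return cfg


@pytest.fixture(scope="session")
def motor_run():
    """One complete motor-task simulation, shared across tests."""
    cfg = _single_chain_cfg(seed=3)
    topo = cs.build_network(cfg)
    scenario = cs.TaskScenario(mode="motor", chains_active=["eat"])
    result = cs.run_motor_task(topo, scenario, cfg, duration=2300.0, seed=3)
    return cfg, topo, scenario, result
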