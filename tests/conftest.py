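"""Shared fixtures: a scaled-down synthetic dataset used across modules."""

import pytest

from chipgas.synth import SimulationConfig, generate_truth, simulate_tags


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=42,
        genome_length=120_000,
        n_isolated_sites=60,
        n_repeat_copies=12,
        n_control_repeat_copies=10,
        n_nonrepeat_tandems=10,
        depth=60,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def stim_tags(small_truth):
    return simulate_tags(small_truth, "stimulated")


@pytest.fixture(scope="session")
def unstim_tags(small_truth):
    return simulate_tags(small_truth, "unstimulated")
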