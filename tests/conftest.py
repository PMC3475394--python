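"""Shared fixtures: reference flask scenario, cached simulations, synthetic data.

The reference condition throughout is the 1% headspace O2 / 1 mM nitrite
flask.  Expensive objects (trajectories, measurement sets) are
session-scoped so the suite simulates each condition once.
"""


import pytest

from denitmod import (
    EnzymeSynthesisParams,
    KineticParams,
    PhysicalParams,
    simulate,
)
from denitmod.synthetic import NoiseModel, generate_measurements, scenario


@pytest.fixture(scope="session")
def reference_config():
    return scenario("nitrite_1mM_o2_1pct")


@pytest.fixture(scope="session")
def default_params():
    return KineticParams(), EnzymeSynthesisParams(), PhysicalParams()


@pytest.fixture(scope="session")
def reference_trajectory(reference_config):
    return simulate(reference_config)


@pytest.fixture(scope="session")
def noiseless_obs(reference_config, reference_trajectory):
    return generate_measurements(
        reference_config,
        noise=NoiseModel(sigma=0.0, seed=0),
        trajectory=reference_trajectory,
    )


@pytest.fixture(scope="session")
def noisy_obs(reference_config, reference_trajectory):
    """5% proportional Gaussian noise, fixed seed."""
    return generate_measurements(
        reference_config,
        noise=NoiseModel(sigma=0.05, seed=1),
        trajectory=reference_trajectory,
    )
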