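import numpy as np
import pytest

from hervitope.sim import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort for sequence- and pipeline-level tests."""
    return SimulationConfig(
        n_hervs=50,
        n_tumor=20,
        n_normal=10,
        planted_cah_effects={f"herv_{i:04d}": 2.0 for i in range(1, 11)},
        planted_cyt_ids=tuple(f"herv_{i:04d}" for i in range(1, 6)),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
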