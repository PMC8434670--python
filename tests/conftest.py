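import logging

import pytest

from silogrowth import ScenarioConfig, process_batch, simulate

logging.getLogger("silogrowth").setLevel(logging.ERROR)


def scenario(**kwargs) -> ScenarioConfig:
    return ScenarioConfig(**kwargs)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Anomaly-free 18-week, 600-pig batch with a perfect sensor."""
    return simulate(ScenarioConfig(seed=11, noise_sd_fraction=0.0, missing_probability=0.0))


@pytest.fixture(scope="session")
def noise_free_result(noise_free_sim):
    return process_batch(noise_free_sim.series, noise_free_sim.batch)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same batch under the default study conditions (1% noise, 2% missing)."""
    return simulate(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    return process_batch(noisy_sim.series, noisy_sim.batch)
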