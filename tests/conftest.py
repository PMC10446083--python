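import numpy as np
import pytest

from pocpipe import SyntheticConfig, generate_cruise, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """A compact but fully featured cruise: 24 stations, 6 runs."""
    return SyntheticConfig(n_stations=24, n_runs=6, unstable_run_ids=(3,),
                           rng_seed=42)


@pytest.fixture(scope="session")
def small_cruise(small_config):
    return generate_cruise(small_config)


@pytest.fixture(scope="session")
def small_result(small_cruise):
    dataset, _ = small_cruise
    return run_pipeline(dataset)


@pytest.fixture(scope="session")
def noise_free_cruise():
    cfg = SyntheticConfig(n_stations=24, n_runs=6, rng_seed=7).noise_free()
    return generate_cruise(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
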