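import numpy as np
import pytest

from msbridge.synthetic_data import ScenarioConfig, build_scenario


@pytest.fixture(scope="session")
def scenario():
    """One deterministic full scenario shared by integration tests."""
    return build_scenario(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Scenario with zero ppm noise and no decoys (exact-mass pipeline checks)."""
    return build_scenario(ScenarioConfig(seed=11, ppm_noise_sd=0.0, n_decoys=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
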