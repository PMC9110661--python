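import numpy as np
import pytest

from pulsewave import SimulationConfig, run_pipeline


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default study conditions (one seed)."""
    return run_pipeline(seed=11)


@pytest.fixture(scope="session")
def control_result():
    """Full pipeline on the mixed-parameter negative control."""
    return run_pipeline(seed=11, control_mix=True)


@pytest.fixture(scope="session")
def noiseless_result():
    cfg = SimulationConfig(seed=5, noise_sigma=0.0)
    return run_pipeline(seed=5, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
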