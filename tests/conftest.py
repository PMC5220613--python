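import numpy as np
import pytest

from misim import DGPConfig, generate_complete


@pytest.fixture(scope="session")
def default_config():
    return DGPConfig(n=1000)


@pytest.fixture(scope="session")
def big_cohort():
    """One large cohort shared by the moment-convergence checks."""
    cfg = DGPConfig(n=400_000, seed=20240)
    return generate_complete(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(915)
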