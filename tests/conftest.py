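import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from jmsched import SimulationConfig, default_params  # noqa: E402


@pytest.fixture(scope="session")
def published_params():
    """Generative parameters built from the published joint-model estimates
    (fixed effects, residual SDs, association and covariate coefficients)
    with the package's assumed random-effects covariance."""
    return default_params()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250921)
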