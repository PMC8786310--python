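import numpy as np
import pytest

from prepmvpa.design import generate_experiment
from prepmvpa.hrf import HRFParams


@pytest.fixture(scope="session")
def hrf_params():
    return HRFParams()


@pytest.fixture(scope="session")
def ten_run_design():
    return generate_experiment(10, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(98765)
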