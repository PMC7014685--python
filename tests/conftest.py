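import numpy as np
import pytest

import rodcascade as rc


@pytest.fixture(scope="session")
def params():
    return rc.load_params()


@pytest.fixture(scope="session")
def dark(params):
    return rc.solve_dark_state(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
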