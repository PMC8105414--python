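import warnings

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _silence_stability_warnings():
    # conditioning-scale eta sits exactly at the averaging bound by design
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="eta=.*")
        yield
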