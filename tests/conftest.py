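import warnings

import numpy as np
import pandas as pd
import pytest

import airimpute as ai


@pytest.fixture(scope="session")
def small_config():
    """Five stations, 400 days: big enough for forests, quick to generate."""
    return ai.default_config(n_days=400, seed=11)


@pytest.fixture(scope="session")
def small_panels(small_config):
    return ai.generate_study(small_config)


@pytest.fixture(scope="session")
def work_panels(small_config):
    """Log-scale panels with PM10 dropped — the pipeline's working form."""
    return ai.prepare_study(ai.StudyConfig(panel=small_config))


@pytest.fixture()
def bivariate():
    """y = x + N(0, 0.1^2), n = 500; strong signal for recovery checks."""
    def make(seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500)
        y = x + rng.normal(scale=0.1, size=500)
        return pd.DataFrame({"x": x, "y": y})
    return make


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
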