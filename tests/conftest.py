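import logging
import warnings

import numpy as np
import pytest

from contits.series_core import TimeSeries

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="statsmodels")
logging.getLogger("contits").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise(rng):
    return TimeSeries(rng.normal(size=200), period=1, label="white noise")


@pytest.fixture
def ar1_series(rng):
    from contits.synthetic import generate_arma
    return TimeSeries(generate_arma(5000, phi=(0.5,), sd=1.0, seed=11))
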