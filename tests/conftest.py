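import numpy as np
import pytest

from demicwave import synthetic
from demicwave.radiocarbon import C14Determination


@pytest.fixture(scope="session")
def identity_curve():
    """Identity calibration curve with zero curve error: analytic checks exact."""
    return synthetic.toy_curve((0, 8000), 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def uniform_grid():
    """Small uniform landscape, all cells settleable."""
    return synthetic.synth_landscape(60, 60, "uniform", value=0.7)


def make_record(site_id="S1", lon=-60.0, lat=-5.0, age=3000.0, sigma=50.0, **kw):
    return C14Determination(site_id=site_id, lon=lon, lat=lat, age=age, sigma=sigma, **kw)


@pytest.fixture
def record_factory():
    return make_record
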