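import numpy as np
import pytest

from glandeis.materials import default_materials


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def thyroid_baseline():
    """Mean-morphology thyroid draw (fascia mid-range)."""
    return {
        "xcell": 8.53,
        "ycell": 8.53,
        "dECS": 0.3,
        "dfollicle": 113.77,
        "dCT": 1.65,
        "dfascia": 0.2625,
    }


@pytest.fixture(scope="session")
def parathyroid_baseline():
    return {
        "xcell": 7.59,
        "ycell": 7.59,
        "dECS": 0.65,
        "dfascia": 0.2625,
        "dpara": 5.5,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
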