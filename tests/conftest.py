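import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ocuphys.rf_mapping import StimulusGrid
from ocuphys.saccades import PolarBinning
from ocuphys.signals import EyeTrace

settings.register_profile(
    "ci", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return StimulusGrid()


@pytest.fixture
def binning():
    return PolarBinning()


def make_trace(x, y=None, rate_hz=1000.0, unit="degrees"):
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    t = np.arange(len(x)) * (1000.0 / rate_hz)
    return EyeTrace(t=t, x=x, y=np.asarray(y, dtype=float), unit=unit,
                    rate_hz=rate_hz)


@pytest.fixture
def make_trace_factory():
    return make_trace
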