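import numpy as np
import pytest

from tfridge.grids import TFDGrid
from tfridge.pipeline import Pipeline


@pytest.fixture(scope="session")
def cheap_pipeline():
    """EMBD-only pipeline: fast enough for per-test use at Nt = 128."""
    return Pipeline(tfd_method="embd")


@pytest.fixture(scope="session")
def cheap_params(cheap_pipeline):
    return cheap_pipeline.localization_params(128)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tone(n, f0=0.1, amplitude=1.0):
    return amplitude * np.cos(2 * np.pi * f0 * np.arange(n))


def chirp(n, f_start, f_stop):
    law = f_start + (f_stop - f_start) * np.arange(n) / n
    return np.cos(2 * np.pi * np.cumsum(law)), law


def grid_of(values, kind="qtfd"):
    return TFDGrid(values=np.asarray(values, float), kind=kind)
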