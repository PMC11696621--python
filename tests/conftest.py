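import numpy as np
import pytest

from enorms.core import MeasurementSeries
from enorms.io import RawColumn


@pytest.fixture
def worked_series() -> MeasurementSeries:
    """Five-point series whose plateau is the 20.0–20.2 run."""
    return MeasurementSeries(
        values=np.array([10.0, 20.0, 20.1, 20.2, 30.0]), label="demo", resolution=0.1
    )


@pytest.fixture
def worked_raw() -> RawColumn:
    """Same data, unsorted, as read from a file."""
    return RawColumn(values=[30.0, 10.0, 20.1, 20.0, 20.2], label="demo")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
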