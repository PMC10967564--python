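import numpy as np
import pandas as pd
import pytest

from barncast.preprocessing import RawSeries


def make_series(values: dict[str, list | np.ndarray]) -> RawSeries:
    """Build a RawSeries on a 30-minute grid from plain channel arrays."""
    n = len(next(iter(values.values())))
    index = pd.date_range("2023-07-01", periods=n, freq="30min", name="timestamp")
    return RawSeries(pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()},
                                  index=index))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_series(rng):
    return make_series(
        {
            "temp": 20 + rng.standard_normal(120),
            "nh3": 10 + rng.standard_normal(120),
        }
    )
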