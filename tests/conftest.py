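import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aeropollen import TaxonSeries

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def uniform_100() -> TaxonSeries:
    """1.0 grains/m^3 on the first 100 days of 2018, nothing after."""
    idx = pd.date_range("2018-01-01", periods=100, freq="D")
    return TaxonSeries(site="test", taxon="Uniform", values=pd.Series(1.0, index=idx))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def naive_mps(values: pd.Series, lower: float = 0.05, upper: float = 0.95):
    """Brute-force cumulative scan for the 90%-method season bounds."""
    total = float(values.sum())
    run = 0.0
    start = end = None
    for date, v in values.items():
        run += v
        if start is None and run >= lower * total:
            start = date
        if end is None and run >= upper * total:
            end = date
            break
    return start, end
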