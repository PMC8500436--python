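import numpy as np
import pytest

from hrvscaling import RRSeries, SeriesSpec, synth_powerlaw_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_series():
    return RRSeries(np.array([800.0, 860.0, 865.0, 800.0]))


@pytest.fixture(scope="session")
def pink_series():
    """One long exact-spectrum beta=1 series (no quantization)."""
    return synth_powerlaw_series(
        SeriesSpec(n=2**16, beta=1.0, quantization_ms=None, seed=42)
    )
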