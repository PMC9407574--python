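import numpy as np
import pytest

from ctmi import EstimatorConfig, SearchSpace, TimeSeriesPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """Two autocorrelated series, X causing Y at lag 2."""
    n = 300
    x = np.zeros(n)
    y = np.zeros(n)
    e = rng.normal(size=(n, 2))
    for t in range(1, n):
        x[t] = 0.5 * x[t - 1] + e[t, 0]
        y[t] = 0.5 * y[t - 1] + (x[t - 2] if t >= 2 else 0.0) + e[t, 1]
    return TimeSeriesPanel({"X": x, "Y": y})


@pytest.fixture
def fast_cfg():
    return EstimatorConfig(k=5, permutations=20, alpha=0.05, seed=0)


@pytest.fixture
def small_space():
    return SearchSpace(gamma_max=3)
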