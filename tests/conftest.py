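import numpy as np
import pandas as pd
import pytest

from plumemix import SyntheticConfig, generate_surface_samples


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def default_samples(default_config):
    return generate_surface_samples(default_config)


@pytest.fixture
def linear_series():
    """Perfectly linear annual series: value = 2 + 0.1 * (year - 1985)."""
    years = np.arange(1985, 2020)
    return pd.DataFrame({"year": years, "value": 2.0 + 0.1 * (years - 1985)})


def ar1(n, rho, sd, rng):
    """Reference AR(1) simulator used as an independent oracle in tests."""
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = rho * out[t - 1] + rng.normal(0.0, sd * np.sqrt(1 - rho ** 2))
    return out
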