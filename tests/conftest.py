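import numpy as np
import pandas as pd
import pytest

from ecoaxes import synthetic


@pytest.fixture(scope="session")
def truth():
    return synthetic.SiteTruth(seed=7)


@pytest.fixture(scope="session")
def drivers_year(truth):
    return synthetic.simulate_drivers(365, truth)


@pytest.fixture(scope="session")
def fluxes_year(drivers_year, truth):
    """Noiseless one-year flux table plus generator internals."""
    return synthetic.simulate_fluxes(drivers_year, truth, with_noise=False,
                                     return_internals=True)


@pytest.fixture(scope="session")
def half_hourly_index():
    def make(days, start="2001-01-01"):
        return pd.date_range(start, periods=days * 48, freq="30min",
                             name="timestamp")
    return make


def quantile_oracle(values, q):
    """Brute-force sort-and-interpolate sample quantile (linear between order
    statistics), independent of numpy's implementation."""
    s = sorted(float(v) for v in values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q
    f = int(np.floor(h))
    if f >= n - 1:
        return s[-1]
    return s[f] + (h - f) * (s[f + 1] - s[f])


@pytest.fixture(scope="session")
def oracle_quantile():
    return quantile_oracle
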