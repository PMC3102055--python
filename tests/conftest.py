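import pytest

from metshift import (
    activity_trend,
    default_anchor_set,
    generate_employment_series,
    met_table_default,
)


@pytest.fixture(scope="session")
def anchors():
    return default_anchor_set()


@pytest.fixture(scope="session")
def noiseless_series(anchors):
    """The anchored 1960–2008 series with no noise (the drift itself)."""
    return generate_employment_series(anchors, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def met_table():
    return met_table_default()


@pytest.fixture(scope="session")
def noiseless_trend(noiseless_series):
    return activity_trend(noiseless_series)
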