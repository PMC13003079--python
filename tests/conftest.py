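import warnings

import pytest

import schemapop as sp


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="negative implied firing rate clipped"
        )
        yield


@pytest.fixture(scope="session")
def fixtures():
    """The five canonical coding-regime datasets (8 trials per type)."""
    return sp.generate_fixtures(seed=3, n_per_type=8)


@pytest.fixture(scope="session")
def fixtures_large():
    """Same regimes with more trials, for decoding-accuracy checks."""
    return sp.generate_fixtures(seed=11, n_per_type=12)
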