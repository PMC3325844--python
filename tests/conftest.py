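import numpy as np
import pytest

from phaomics import reference


@pytest.fixture(scope="session")
def feeds():
    return reference.feed_media()


@pytest.fixture(scope="session")
def states():
    return reference.steady_state_records()


@pytest.fixture(scope="session")
def published():
    return reference.chemostat_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
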