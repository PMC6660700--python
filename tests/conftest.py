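import numpy as np
import pytest

from mosascan import ThresholdPolicy, load_cohort_fixture


@pytest.fixture(scope="session")
def records():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def proband_records(records):
    return [r for r in records if r.table.value == "proband"]


@pytest.fixture
def policy():
    return ThresholdPolicy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
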