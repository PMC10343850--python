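import numpy as np
import pytest

from cfsaemda.synthetic_data import make_worked_example


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 4x3 fixture: associations, ontology, MFS with one missing pair."""
    return make_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
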