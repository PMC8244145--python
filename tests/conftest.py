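import numpy as np
import pytest

from xciescape import synthetic_data as sd

SEED = 20210629 % (2**31)


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition synthetic dataset shared by read-only tests."""
    return sd.simulate_truth(sd.SimConfig(seed=SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
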