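import numpy as np
import pytest

from motorpair.motor_model import reference_params


@pytest.fixture(scope="session")
def params():
    """Bundled reference parameter table (Kin1/2/3 + DDB)."""
    return reference_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
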