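import numpy as np
import pytest

from flptpm import default_protocol, default_scheme
from flptpm.scheme import ExperimentProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol():
    return default_protocol()


@pytest.fixture
def short_protocol():
    """Abbreviated assay for fast unit tests: ~7 min of recording."""
    return ExperimentProtocol(t_baseline=40.0, t_flp_add=50.0, t_sds=360.0, t_post_sds=40.0)


@pytest.fixture
def direct_scheme():
    return default_scheme("Flpe", "direct")
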