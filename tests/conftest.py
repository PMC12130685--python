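import numpy as np
import pytest

from glymap import phantom as ph


@pytest.fixture(scope="session")
def small_phantom():
    return ph.make_phantom((32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def fast_t2_times():
    return np.asarray(ph.FAST_T2_TIMES_MS)


@pytest.fixture(scope="session")
def dwi_acq():
    return ph.default_acquisition()
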