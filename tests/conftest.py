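import numpy as np
import pytest

from hrvcc.synthetic import SeriesSpec, gen_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_series():
    """A 9000-beat uncorrelated IBI series at ~92 bpm."""
    return gen_series(SeriesSpec(kind="white", n=9000, seed=7)).intervals


@pytest.fixture
def constant_recording():
    from hrvcc.io_filtering import RawIBIRecording

    # 120 min of constant 800 ms intervals
    n = int(120 * 60000 / 800)
    return RawIBIRecording(subject_id="const", intervals=np.full(n, 800.0))
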