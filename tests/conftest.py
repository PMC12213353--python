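import numpy as np
import pytest

from eegage.recording import RawRecording
from eegage.montage import CANONICAL_19


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate=200.0, age=5.0, subject="s0"):
    n_chan = data.shape[0]
    labels = CANONICAL_19[:n_chan] if n_chan <= 19 else tuple(f"ch{i}" for i in range(n_chan))
    return RawRecording(
        data=data, rate=rate, channel_labels=labels, subject_id=subject, age_years=age
    )


@pytest.fixture
def random_recording(rng):
    """19-channel, 10-s recording of N(0, 50 uV) noise at 200 Hz."""
    return make_recording(rng.normal(0.0, 50.0, size=(19, 2000)))
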