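import numpy as np
import pytest

from cytolite import ChannelInfo, Sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def make_sample():
    """Factory for small in-memory samples with named channels."""

    def _make(events, names=None, **kwargs):
        events = np.asarray(events, dtype=float)
        if names is None:
            names = [f"FL{i + 1}" for i in range(events.shape[1])]
        channels = [ChannelInfo(n) for n in names]
        return Sample(events, channels, **kwargs)

    return _make
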