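import numpy as np
import pytest

from gazecross.geometry import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(x, y, valid=None, rate_hz=1000.0, trial_id="trial", participant_id="p0"):
    """Convenience constructor for hand-built sample streams."""
    from gazecross.io import GazeRecording

    x = np.asarray(x, float)
    n = len(x)
    return GazeRecording(
        participant_id=participant_id,
        trial_id=trial_id,
        t=np.arange(n) * (1000.0 / rate_hz),
        x=x,
        y=np.asarray(y, float),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        rate_hz=rate_hz,
    )
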