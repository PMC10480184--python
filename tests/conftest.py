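import numpy as np
import pytest

from sptfcs import simulate
from sptfcs._tracks import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A small, fast simulation configuration (benchmark acquisition settings)."""
    return simulate.SimulationConfig(n_tracks=100, rng_seed=7)


def make_track(xy, frame_interval=0.01, track_id=0):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(
        track_id=track_id,
        frames=np.arange(xy.shape[0]),
        xy=xy,
        frame_interval=frame_interval,
    )
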