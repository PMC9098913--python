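import numpy as np
import pytest

from slbkit.core import Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brownian_track(track_id, n_steps, d_coeff, frame_interval,
                   rng, origin=(0.0, 0.0)):
    """Pure Brownian 2D track with per-axis step sd sqrt(2 D dt)."""
    sd = np.sqrt(2.0 * d_coeff * frame_interval)
    steps = rng.normal(0.0, sd, (n_steps, 2))
    pos = np.vstack([[origin], origin + np.cumsum(steps, axis=0)])
    return Track(track_id=track_id, frames=np.arange(n_steps + 1),
                 x=pos[:, 0], y=pos[:, 1], frame_interval=frame_interval)
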