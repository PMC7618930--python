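import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trajseg import Trajectory

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(rng, length, track_id="t0", labelled=True):
    coords = np.cumsum(rng.normal(size=(length, 2)), axis=0)
    labels = rng.integers(0, 2, size=length) if labelled else None
    return Trajectory(
        track_id=track_id,
        frames=np.arange(length),
        coords=coords,
        labels=labels,
    )


@pytest.fixture
def small_tracks(rng):
    """A handful of labelled random-walk tracks of mixed lengths."""
    return [
        make_trajectory(rng, L, track_id=f"t{i}")
        for i, L in enumerate([5, 8, 12, 20, 33])
    ]
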