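import numpy as np
import pytest

from ethotype import ArenaConfig, Track


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_random_track(rng, n=100, duration=3600, lo=0.0, hi=800.0,
                      id="T000", trial=1, test="activity"):
    """Random detections at sorted distinct seconds, for brute-force oracles."""
    t = np.sort(rng.choice(duration, size=n, replace=False))
    return Track(id=id, trial=trial, test=test, duration_s=duration,
                 t_s=t, x_px=rng.uniform(lo, hi, n), y_px=rng.uniform(lo, hi, n))


@pytest.fixture
def random_track(rng):
    return make_random_track(rng)
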