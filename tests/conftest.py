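import numpy as np
import pytest

import sofikit as sk


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_movie(rng):
    """50-frame 6x7 movie of positive camera-like values."""
    return sk.Movie(rng.gamma(shape=3.0, scale=50.0, size=(50, 6, 7)))


@pytest.fixture
def single_emitter_movie(rng):
    """One blinking emitter at a pixel center, no noise, with ground truth."""
    field = sk.EmitterField(positions=[(10.0, 10.0)], brightness=100.0,
                            on_ratio=0.3)
    movie, truth = sk.simulate_movie(field, sk.PsfModel(sigma=1.5),
                                     frames=5000, shape=(21, 21), seed=rng)
    return movie, truth
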