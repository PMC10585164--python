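import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def worked_2x2():
    """The 2x2 hand-evaluated fixture: one foreground pixel, confident but
    imperfect prediction."""
    mask = np.array([[1.0, 0.0], [0.0, 0.0]])
    prob = np.array([[0.8, 0.2], [0.1, 0.1]])
    return prob, mask


def random_prob_mask(rng, shape=(12, 12), fg=0.25):
    prob = rng.uniform(0.0, 1.0, shape)
    mask = (rng.random(shape) < fg).astype(float)
    return prob, mask
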