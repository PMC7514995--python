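import numpy as np
import pandas as pd
import pytest

from oinet.containers import RsaSeries
from oinet.reconstruction import build_group


def make_series(matrix, individual_id="x", species=None):
    matrix = np.asarray(matrix, dtype=float)
    species = species or [f"sp{i}" for i in range(matrix.shape[0])]
    return RsaSeries.from_frame(individual_id, pd.DataFrame(matrix, index=species))


def make_group(matrix, group_id="g", species=None):
    return build_group([make_series(matrix, species=species)], group_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain_series(rng):
    """Three-species chain X -> Y -> Z: noisy copies at lag 1."""
    t = 500
    x = rng.integers(0, 2, size=t).astype(float)
    flip = lambda s: np.where(rng.random(t) < 0.15, 1 - s, s)
    y = flip(np.roll(x, 1))
    z = flip(np.roll(y, 1))
    return x, y, z
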