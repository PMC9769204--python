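import numpy as np
import pytest

from petrad.imaging import SUV, Volume, VoiMask
from petrad.radiomics.discretize import DiscretizationConfig, DiscretizedVOI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_discretized_voi(rng, shape=(5, 5, 5), n_levels=4, p_mask=0.7) -> DiscretizedVOI:
    """A random small discretized VOI for matrix oracle tests."""
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedVOI(
        levels=levels,
        mask=mask,
        n_levels=n_levels,
        spacing=(4.0, 4.0, 4.0),
        config=DiscretizationConfig(),
    )


def uniform_voi_volume(value=8.0, n=(5, 5, 4), spacing=(4.0, 4.0, 4.0)):
    """A uniform-uptake volume whose VOI covers the whole grid."""
    data = np.full(n, float(value))
    vol = Volume(data=data, spacing=spacing, units=SUV)
    voi = VoiMask(mask=np.ones(n, dtype=bool), spacing=spacing)
    return vol, voi
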