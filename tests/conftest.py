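import warnings

import numpy as np
import pytest

from accca.synth import DEFAULT_STAIN_MATRIX, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stain_matrix():
    return DEFAULT_STAIN_MATRIX.copy()


@pytest.fixture(scope="session")
def small_scene():
    """96x96 scene with 3 well-separated nuclei, no noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scene(96, 96, 3, overlap_fraction=0.0,
                              noise_sd=0.0, seed=7)


def disk(shape, center, radius):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rows - center[0], cols - center[1]) <= radius
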