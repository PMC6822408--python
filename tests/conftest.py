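import numpy as np
import pytest

from paniclecount.preprocess import PreprocessConfig
from paniclecount.synthetic import SyntheticSpec, render_panicle

#: quarter of the full 2480x3507 scanner frame; fast enough for tests
TEST_SCALE = 0.25


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """Default generator conditions shrunk to the quarter-scale frame."""
    return SyntheticSpec(seed=7).at_scale(TEST_SCALE)


@pytest.fixture(scope="session")
def small_cfg():
    return PreprocessConfig().at_scale(TEST_SCALE)


@pytest.fixture(scope="session")
def small_panicle(small_spec):
    return render_panicle(small_spec)


def random_blob_mask(seed: int, shape=(64, 64), density: float = 0.35) -> np.ndarray:
    """Random Bernoulli mask; clumpy enough to have multi-pixel components."""
    r = np.random.default_rng(seed)
    return r.random(shape) < density
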