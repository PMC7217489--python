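import numpy as np
import pytest

from scmirac.matrix_core import CountMatrix
from scmirac.synthetic_data import worked_fixture


@pytest.fixture
def fixture_sim():
    """Tiny deterministic 12x6 two-cluster dataset with hand-placed dropouts."""
    return worked_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """20 cells x 15 genes of Poisson counts, two shifted groups."""
    X = rng.poisson(4.0, size=(20, 15)).astype(float)
    X[10:, :5] += 12
    return CountMatrix(X)
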