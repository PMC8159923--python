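import numpy as np
import pytest

from kmimpute import AnnotatedMatrix

NA = np.nan


def matrix(rows, **kwargs) -> AnnotatedMatrix:
    """AnnotatedMatrix from a list of rows; NaN entries become the mask."""
    return AnnotatedMatrix(values=np.array(rows, dtype=float), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def rank1_complete(rng):
    """Noiseless rank-1 5×4 matrix with positive effects."""
    r = rng.uniform(1.0, 3.0, 5)
    c = rng.uniform(1.0, 3.0, 4)
    return np.outer(r, c)
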