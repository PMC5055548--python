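import numpy as np
import pytest
from hypothesis import settings

from pseudoprog.dictlearn import StructuredDictionary

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def normalized_columns(rng, m, n):
    """Random centered unit-norm patch-like columns."""
    Y = rng.standard_normal((m, n))
    Y -= Y.mean(axis=0, keepdims=True)
    return Y / np.linalg.norm(Y, axis=0, keepdims=True)


def random_dictionary(rng, m, Kp, Kt, Ks):
    """Random unit-norm structured dictionary."""
    def block(k):
        D = rng.standard_normal((m, k))
        return D / np.linalg.norm(D, axis=0, keepdims=True) if k else np.empty((m, 0))

    return StructuredDictionary(block(Kp), block(Kt), block(Ks))


@pytest.fixture
def make_columns():
    return normalized_columns


@pytest.fixture
def make_dictionary():
    return random_dictionary
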