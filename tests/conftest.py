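import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_prob_matrix():
    """20 x 3 probability matrix with mixed labels, deterministic."""
    from consvote import ProbabilityMatrix
    gen = np.random.default_rng(7)
    values = gen.random((20, 3))
    labels = gen.integers(0, 2, size=20)
    labels[:2] = [0, 1]  # both classes guaranteed
    ids = [f"c{i}" for i in range(20)]
    return ProbabilityMatrix(ids, ["m0", "m1", "m2"], values, labels)
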