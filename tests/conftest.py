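import numpy as np
import pytest

from nicheneutral import AbundanceMatrix, gen_neutral


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 species x 2 samples with column depths (6, 5)."""
    return AbundanceMatrix(
        counts=np.array([[5, 0], [1, 2], [0, 3]]),
        species_ids=["a", "b", "c"], sample_ids=["t0", "t1"],
        subject_id="tiny")


@pytest.fixture(scope="session")
def neutral_small():
    """A small neutral metacommunity (theta=10, I=10, T=8, depth 500)."""
    mat, manifest = gen_neutral(10.0, 10.0, [500] * 8,
                                rng=np.random.default_rng(7))
    return mat, manifest
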