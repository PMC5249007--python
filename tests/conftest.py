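import numpy as np
import pytest

from antimedian import TrioSpec, random_trio


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def zero_overlap_trio_10k():
    """A zero-overlap trio at n = 10^4, shared by the large-n tests."""
    return random_trio(TrioSpec(n=10_000, seed=42))
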