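import numpy as np
import pytest

from qstrip import default_dna_map


@pytest.fixture(scope="session")
def dna():
    return default_dna_map()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
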