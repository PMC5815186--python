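import numpy as np
import pytest

from pfalign import SynthConfig, generate_dataset, generate_profile_pair
from pfalign.synthetic import random_pssv_block


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """20 desk-scale synthetic pairs (length 40, defaults otherwise)."""
    return generate_dataset(SynthConfig(length=40), 20, seed=11)


@pytest.fixture(scope="session")
def one_pair():
    return generate_profile_pair(SynthConfig(seed=42, length=40))


@pytest.fixture()
def pssv_pair_block():
    r = np.random.default_rng(7)
    return random_pssv_block(r, 0.3, 200), random_pssv_block(r, 0.3, 200)
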