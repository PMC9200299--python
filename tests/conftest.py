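import numpy as np
import pytest

from scabkit import make_fv
from scabkit.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def fv_record():
    """One default-sized synthetic Fv (L=60) with full coordinates."""
    return make_fv(SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def small_record():
    """A small Fv (L=24) for cheap structural tests."""
    return make_fv(SyntheticSpec(heavy_len=16, light_len=8, h3_len=5, seed=7))


@pytest.fixture(scope="session")
def records3():
    """The three default-sized records used by overfitting experiments."""
    return [make_fv(SyntheticSpec(seed=s)) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
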