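import numpy as np
import pytest

from rmdkit import (
    ResolutionParams,
    default_repeat_pair,
    detect_divergent_sites,
)


@pytest.fixture(scope="session")
def pair3():
    """Synthetic 287-bp repeat pair with eight planted substitutions (3%)."""
    return default_repeat_pair("3%")


@pytest.fixture(scope="session")
def sites3(pair3):
    return detect_divergent_sites(pair3)


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type-like resolution parameters (strong nick-directed excision)."""
    return ResolutionParams(pi_b=0.6, pi_t=0.6, theta_b=0.99, theta_t=0.99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
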