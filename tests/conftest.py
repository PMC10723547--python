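import numpy as np
import pytest

from sharederr import CohortDesign, ErrorModel


@pytest.fixture(scope="session")
def design():
    return CohortDesign.default()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_design():
    """Two small groups for brute-force oracles."""
    return CohortDesign(np.array([0.1, 1.0]), np.array([6, 4]))


@pytest.fixture
def berkson_2020():
    return ErrorModel(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2)
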