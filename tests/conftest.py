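import numpy as np
import pytest

from arraypower import StudyDesign, generate_pilot


@pytest.fixture
def design_5pct_70() -> StudyDesign:
    """m=2000, pi1=5%, delta0=2, q*=0.05, lambda0=0.70 reference design."""
    return StudyDesign.from_pi1(2000, 0.05, 2.0, 0.05, 0.70)


@pytest.fixture
def small_pilot():
    """Small synthetic pilot (200 genes, 4+4 samples, 10 differential)."""
    return generate_pilot(m=200, m1=10, delta0=2.0, n0p=4, n1p=4, rng_seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100125)
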