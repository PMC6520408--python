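import numpy as np
import pytest

from cortimech.cohort import CohortConfig, NoiseLevels, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-specimen study cohort at a fixed seed."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def specimen(default_cohort):
    """One mid-porosity specimen."""
    mid = sorted(default_cohort, key=lambda s: s.porosity_true)
    return mid[len(mid) // 2]


@pytest.fixture
def zero_noise():
    return NoiseLevels.zero()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
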