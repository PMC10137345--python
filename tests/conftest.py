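import numpy as np
import pytest
from hypothesis import settings

from genassoc.reference import study_genotype_matrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_cohort():
    """Sample-level genotype matrix matching the published per-group counts."""
    return study_genotype_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)
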