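import numpy as np
import pytest

from historiskscore.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = SyntheticCohortConfig(
        n_cases=150, patches_per_case=(200, 400), seed=42
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
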