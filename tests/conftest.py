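import numpy as np
import pytest

from snconn import SyntheticConfig, generate_cohort
from snconn.synthetic import MediationGroundTruth


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_per_group=15,
        n_timepoints=120,
        planted_edges=[(4, 5, 0.6), (4, 6, 0.6), (5, 6, 0.6)],
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect cohort: exchangeable groups, default mediation noise."""
    cfg = SyntheticConfig(
        n_per_group=12,
        n_timepoints=120,
        mediation=MediationGroundTruth(a=0.0, b=0.0, c_prime=0.0),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
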