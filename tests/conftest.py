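import numpy as np
import pytest

from ordlmi.synthetic import SyntheticConfig, generate_cohort
from ordlmi.polychoric import PolychoricCorrelation


@pytest.fixture(scope="session")
def recovery_config():
    """Four-session design with declining mean and growing variance, the
    workhorse generating model for recovery and mechanism checks."""
    return SyntheticConfig(
        n_subjects=2000,
        n_items=7,
        n_sessions=4,
        latent_means=np.array([0.0, -0.3, -0.6, -0.9]),
        latent_variances=np.array([1.0, 1.2, 1.5, 1.8]),
        loadings=np.full(7, 0.8),
        seed=11,
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_config):
    return generate_cohort(recovery_config)


@pytest.fixture(scope="session")
def recovery_sample(recovery_cohort):
    return PolychoricCorrelation().fit(recovery_cohort)
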