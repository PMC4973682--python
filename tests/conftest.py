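import numpy as np
import pytest
from hypothesis import settings

from promperf.cohort import CohortConfig, MissingnessConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def complete_cohort():
    """Small cohort with missingness switched off: patients == truth."""
    config = CohortConfig(n_providers=15, volume_mean=80, volume_log_sd=0.3,
                          missingness=MissingnessConfig(enabled=False))
    providers, patients, truth = generate_cohort(config, seed=101)
    return config, providers, patients, truth


@pytest.fixture(scope="session")
def mar_cohort():
    """Cohort with MAR questionnaire-level missingness (delta = 0)."""
    config = CohortConfig(n_providers=15, volume_mean=80, volume_log_sd=0.3)
    providers, patients, truth = generate_cohort(config, seed=202)
    return config, providers, patients, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
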