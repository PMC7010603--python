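import warnings

import pytest

from tibload import SimulationConfig, generate_cohort
from tibload.features import assemble_features


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small noiseless cohort: ground truth is exactly recoverable."""
    config = SimulationConfig(
        n_subjects=6,
        trials_per_subject=4,
        noise_sd_accel=0.0,
        noise_sd_force=0.0,
        rng_seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort at the default noise levels."""
    config = SimulationConfig(n_subjects=6, trials_per_subject=4, rng_seed=5)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_features(small_cohort)
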