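import numpy as np
import pytest

from insolecg import (GeneratorConfig, ProtocolConfig, SubjectProfile,
                      generate_trial, prepare_subjects)
from insolecg.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_free_generator():
    return GeneratorConfig(pressure_noise_frac=0.0, cg_noise_mm=0.0)


@pytest.fixture(scope="session")
def young_profile():
    return SubjectProfile(subject_id="y00", group="young", weight=69.6,
                          leg_length=913.0, ml_pv_amplitude=45.25,
                          pd_pv_amplitude=41.36, walking_speed=1.41, seed=7)


@pytest.fixture(scope="session")
def noise_free_trial(young_profile, noise_free_generator):
    return generate_trial(young_profile, trial_seed=42,
                          config=noise_free_generator)


@pytest.fixture(scope="session")
def small_protocol_config():
    """A desk-scale protocol configuration for fast integration tests."""
    return ProtocolConfig(n_young=4, n_old=4, trials_per_subject=2,
                          feature_counts_grid=(5, 10), max_epochs=5)


@pytest.fixture(scope="session")
def small_subjects(small_protocol_config):
    """4 + 4 subjects x 2 trials, preprocessed and featurized."""
    cfg = small_protocol_config
    trials = generate_cohort(cfg.n_young, cfg.n_old, cfg.trials_per_subject,
                             seed=77, config=cfg.generator)
    return prepare_subjects(trials, cfg)
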