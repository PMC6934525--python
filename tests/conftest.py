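import numpy as np
import pytest
from hypothesis import settings

from dualgait.pipeline import simulate_feature_table
from dualgait.synthetic_cohort import CohortConfig, simulate_trial, sample_subjects

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

#: Master seed for the desk-scale study cohort used by the headline checks.
DEFAULT_COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort_table():
    """Feature table of the default study cohort (60 subjects x 20 trials)."""
    cfg = CohortConfig()
    _, table = simulate_feature_table(cfg, np.random.default_rng(DEFAULT_COHORT_SEED))
    return table


@pytest.fixture(scope="session")
def small_cohort_table():
    """A quick 8-subject x 4-trial cohort for structural tests."""
    cfg = CohortConfig(n_subjects=8, trials_per_subject=4)
    _, table = simulate_feature_table(cfg, np.random.default_rng(3))
    return table


@pytest.fixture()
def zero_noise_config():
    """Fully deterministic simulator settings: no noise anywhere, perfect
    arithmetic accuracy, stepping aligned with the 30 Hz frame grid."""
    return CohortConfig(
        mmse_sd=0.0, interval_slope_s=0.0, accuracy_slope=0.0,
        dual_cost_accuracy=0.0,
        subject_amplitude_sd=0.0, subject_interval_sd=0.0,
        subject_jitter_rel_sd=0.0, subject_accuracy_sd=0.0,
        subject_answer_time_sd=0.0,
        base_step_jitter_s=0.0, cycle_amplitude_sd=0.0,
        answer_time_trial_sd=0.0, frame_noise_m=0.0,
        base_accuracy=1.0,
    )


@pytest.fixture()
def zero_noise_session(zero_noise_config):
    subject = sample_subjects(zero_noise_config, np.random.default_rng(0))[0]
    return subject, simulate_trial(subject, 1, zero_noise_config,
                                   np.random.default_rng(1))
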