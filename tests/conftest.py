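import numpy as np
import pytest

from gaitkinetics.synthetic import (
    NoiseConfig,
    generate_stance_trial,
    generate_subject,
    generate_subject_trials,
)

SILENT = NoiseConfig(0, 0, 0, 0, 0)


@pytest.fixture(scope="session")
def subject():
    return generate_subject(11)


@pytest.fixture(scope="session")
def noiseless_trial(subject):
    return generate_stance_trial(subject, 3, SILENT)


@pytest.fixture(scope="session")
def noiseless_trials(subject):
    """Four noiseless trials of the session subject."""
    return generate_subject_trials(subject, 4, SILENT, base_trial_seed=50)


@pytest.fixture(scope="session")
def noisy_trials(subject):
    """The subject's four-trial set at the default measurement noise."""
    return generate_subject_trials(subject, 4, NoiseConfig(), base_trial_seed=50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
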