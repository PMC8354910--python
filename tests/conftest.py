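import numpy as np
import pytest

from restdecode.decoder import extract_trials, train_decoder
from restdecode.preprocess import preprocess_task_run
from restdecode.synthgen import SimConfig, generate_subject


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale subject: few voxels/sessions, short rest run."""
    return SimConfig(
        n_voxels=60,
        n_sessions=3,
        rest_scans=80,
        task_amplitude=3.0,
        noise_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def subject(small_config):
    return generate_subject(small_config)


@pytest.fixture(scope="session")
def subject_trials(subject):
    trials = None
    for run, labels, nuis in zip(subject.task_runs, subject.schedules, subject.task_nuisance):
        ts = extract_trials(preprocess_task_run(run, nuis), labels)
        trials = ts if trials is None else trials.concat(ts)
    return trials


@pytest.fixture(scope="session")
def trained_model(subject_trials):
    return train_decoder(subject_trials, lam=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
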