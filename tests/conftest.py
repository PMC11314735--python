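import dataclasses

import numpy as np
import pytest

from ltest.io_model import PipelineConfig
from ltest.preprocess import preprocess_trial
from ltest.subtask_windows import extract_all_subtasks
from ltest.synthetic import SyntheticTrialSpec, generate_cohort, generate_trial


def zero_noise_spec(**kwargs) -> SyntheticTrialSpec:
    base = SyntheticTrialSpec(**kwargs)
    return dataclasses.replace(
        base, noise_sigma={k: 0.0 for k in base.noise_sigma}
    )


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticTrialSpec(seed=7)


@pytest.fixture(scope="session")
def clean_spec():
    return zero_noise_spec(seed=7)


@pytest.fixture(scope="session")
def clean_trial(clean_spec):
    return generate_trial(clean_spec)


@pytest.fixture(scope="session")
def default_trial(default_spec):
    return generate_trial(default_spec)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_datasets(clean_trial, config):
    """The six subtask datasets of one clean trial."""
    trial, gt = clean_trial
    pt = preprocess_trial(trial, config)
    return extract_all_subtasks(pt, gt, config.subtask_ranges)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for pipeline-level tests: 2 amputees, 1 able participant."""
    base = zero_noise_spec().scaled(time_scale=0.3)
    return generate_cohort(2, 1, base_spec=base, seed=5)
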