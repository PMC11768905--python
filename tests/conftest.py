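import numpy as np
import pytest

from gaitsmooth import PipelineConfig, SyntheticGaitSpec, generate_trial
from gaitsmooth.pipeline import process_trial


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig().validate()


@pytest.fixture(scope="session")
def clean_trial():
    """Noise- and jitter-free trial: every stride is identical by construction."""
    spec = SyntheticGaitSpec(n_strides=8, noise_sd=0.0, cadence_jitter=0.0, seed=0)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def noisy_trial():
    spec = SyntheticGaitSpec(n_strides=6, noise_sd=0.05, cadence_jitter=0.02, seed=1)
    return generate_trial(spec)


@pytest.fixture(scope="session")
def processed_cohort(default_config):
    """20 processed trials with ground truth, shared across statistics tests."""
    out = []
    for seed in range(20):
        spec = SyntheticGaitSpec(n_strides=8, noise_sd=0.05, cadence_jitter=0.02,
                                 n_submovements=1, seed=100 + seed)
        trial, truth = generate_trial(spec, subject_id=f"S{seed:02d}",
                                      trial_id=f"T{seed:02d}")
        out.append((process_trial(trial, default_config), truth))
    return out
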