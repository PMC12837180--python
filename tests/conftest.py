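import numpy as np
import pytest

from gaitband.ik import solve_trajectory_ik
from gaitband.model import default_model
from gaitband.synthetic import SyntheticConfig, make_default_templates, synthesize_trial


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def templates(model):
    return make_default_templates(model)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free self-selected-speed walk, 4 strides at 60 Hz."""
    return SyntheticConfig(n_strides=4, marker_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_trial(clean_config, templates, model):
    return synthesize_trial(clean_config, templates=templates, model=model)


@pytest.fixture(scope="session")
def clean_ik(clean_trial, model):
    markers, _ = clean_trial
    return solve_trajectory_ik(model, markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
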