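import numpy as np
import pytest
from hypothesis import settings

from latkin import EventGenConfig, SuccessModel, generate_event_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth_model() -> SuccessModel:
    """Reference discrimination function: 0.25 plateau, 2 steps, 24 s half-max."""
    return SuccessModel.from_half_max(0.25, 2.0, 24.0)


@pytest.fixture(scope="session")
def event_table(truth_model):
    """Continuous-dwell synthetic ensemble at the measured MCC scale."""
    cfg = EventGenConfig(k_off=1.0 / 23.8, k_bleach=0.0, plat_model=truth_model,
                         n_events=1071, t_resolution=0.0, seed=42)
    return generate_event_table(cfg)


@pytest.fixture(scope="session")
def bleached_table(truth_model):
    """Ensemble with photobleach censoring: k_obs = k_off + k_bleach."""
    cfg = EventGenConfig(k_off=1.0 / 44.0, k_bleach=1.0 / 99.0,
                         plat_model=truth_model, n_events=2000,
                         t_resolution=0.0, seed=7)
    return generate_event_table(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
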