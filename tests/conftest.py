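import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smrloop as sl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning,
                                module="scipy")
        yield


@pytest.fixture(scope="session")
def small_eeg():
    """Five-trial default-SNR session with a 30% task alpha attenuation."""
    return sl.generate_eeg_session(
        sl.EEGSimConfig(n_trials=5, erd_depth=0.3, seed=101)
    )


@pytest.fixture(scope="session")
def clean_eeg():
    """Noise-free, background-free oscillatory session (analytic case)."""
    cfg = sl.EEGSimConfig(
        n_trials=3, erd_depth=0.3, seed=102,
        aperiodic_offset=-np.inf, noise_sd=0.0,
    )
    return sl.generate_eeg_session(cfg)


@pytest.fixture(scope="session")
def sep_session():
    return sl.generate_sep_session(sl.SEPSimConfig(n_stimuli=200, seed=103))
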