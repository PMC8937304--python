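import numpy as np
import pytest

from obmix.synthetic import (
    DEFAULT_ODOUR_IDS,
    DEFAULT_OVERLAPS,
    STATE_PRESETS,
    StateProfile,
    SyntheticConfig,
    make_panel,
    make_trial_list,
    simulate_session,
)
from obmix.transients import build_response_matrix


@pytest.fixture(scope="session")
def panel():
    """Default 11-odour panel with graded target overlap, 100 ROIs."""
    return make_panel(100, 11, DEFAULT_OVERLAPS, seed=101)


@pytest.fixture(scope="session")
def noiseless_linear_session(panel):
    """Noise-free, linearly summing session: every amplitude is exact."""
    state = StateProfile(name="noiseless", gain=1.0, trial_noise_sd=0.0)
    cfg = SyntheticConfig(
        trial_list=make_trial_list(panel, n_blocks=4, seed=102),
        seed=103,
        frame_noise_sd=0.0,
    )
    return simulate_session(panel, state, cfg)


@pytest.fixture(scope="session")
def anaesthetised_session(panel):
    """Saturating, low-noise session under the anaesthetised preset."""
    cfg = SyntheticConfig(
        trial_list=make_trial_list(panel, n_blocks=6, seed=104),
        seed=105,
    )
    return simulate_session(panel, STATE_PRESETS["anaesthetised"], cfg)


@pytest.fixture(scope="session")
def anaesthetised_rm(anaesthetised_session):
    return build_response_matrix(
        anaesthetised_session, (0.0, 1.0), target="EB", masker="MB"
    )


@pytest.fixture(scope="session")
def noiseless_rm(noiseless_linear_session):
    return build_response_matrix(
        noiseless_linear_session, (0.0, 1.0), target="EB", masker="MB"
    )
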