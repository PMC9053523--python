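import numpy as np
import pytest

from sptstates import BrownianSimConfig, simulate_bm_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def two_state_tracks():
    """Small two-state Brownian mixture shared by several test modules."""
    cfg = BrownianSimConfig(
        n_tracks=100,
        track_length=50,
        diffusion_coefficients=[0.135, 1.8],
        transition_matrix=[[0.95, 0.05], [0.05, 0.95]],
        tau=0.02,
        seed=555,
    )
    return simulate_bm_tracks(cfg)
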