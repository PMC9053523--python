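"""Canonical simulated validation regimes.

These are the study conditions used throughout the validation suite: a
two-state Brownian mixture with D = 0.135 and 1.8 µm²/s, its sparse and
motion-blur variants, a two-state BM + subdiffusive-FBM mixture with
apparent D = 0.045 and 0.90 µm²/s (FBM exponent 0.5), and a four-state
BM/FBM mixture.  Transition matrices use symmetric self-transition-dominant
rows (0.95 for the two-state regimes, 0.91 for the four-state one), giving
uniform stationary weights.  The frame interval is 0.02 s (50 frames/s)
and the motion-blur variant averages 10 sub-steps per exposure with 30 nm
localization noise.
"""

from __future__ import annotations

import numpy as np

from .anomalous import simulate_mixed_type_tracks
from .brownian import (
    BrownianSimConfig,
    simulate_bm_tracks,
    simulate_motion_blur_tracks,
)

TAU = 0.02  # s

TWO_STATE_D = (0.135, 1.8)  # µm²/s
TWO_STATE_P = ((0.95, 0.05), (0.05, 0.95))

BM_FBM_D = (0.045, 0.90)  # µm²/s; slower state is FBM
BM_FBM_ALPHA = 0.5

FOUR_STATE_SPECS = (
    {"type": "FBM", "D": 0.04, "alpha": 0.5},
    {"type": "BM", "D": 0.2},
    {"type": "BM", "D": 0.8},
    {"type": "FBM", "D": 3.0, "alpha": 1.3},
)

TEXP = 10
LOC_SIGMA = 0.03  # µm

ABUNDANT = (500, 100)  # (n_tracks, track_length)
SPARSE = (2000, 10)


def two_state_standard(n_tracks=500, track_length=100, seed=0):
    """Two-state Brownian mixture, no motion blur."""
    cfg = BrownianSimConfig(
        n_tracks=n_tracks,
        track_length=track_length,
        diffusion_coefficients=list(TWO_STATE_D),
        transition_matrix=np.asarray(TWO_STATE_P),
        tau=TAU,
        seed=seed,
    )
    return simulate_bm_tracks(cfg)


def two_state_motion_blur(n_tracks=500, track_length=100, seed=0):
    """Two-state Brownian mixture with exposure averaging + 30 nm noise."""
    cfg = BrownianSimConfig(
        n_tracks=n_tracks,
        track_length=track_length,
        diffusion_coefficients=list(TWO_STATE_D),
        transition_matrix=np.asarray(TWO_STATE_P),
        tau=TAU,
        texp=TEXP,
        localization_sigma=LOC_SIGMA,
        seed=seed,
    )
    return simulate_motion_blur_tracks(cfg)


def bm_fbm_mixture(n_tracks=500, track_length=100, seed=0):
    """Two-state mixture: subdiffusive FBM (slow) + BM (fast)."""
    specs = [
        {"type": "FBM", "D": BM_FBM_D[0], "alpha": BM_FBM_ALPHA},
        {"type": "BM", "D": BM_FBM_D[1]},
    ]
    return simulate_mixed_type_tracks(
        specs,
        np.asarray(TWO_STATE_P),
        n_tracks,
        track_length,
        TAU,
        np.random.default_rng(seed),
        seed=seed,
    )


def four_state_mixture(n_tracks=500, track_length=100, seed=0):
    """Four states ascending in D: subdiffusive FBM, BM, BM, superdiffusive FBM."""
    K = len(FOUR_STATE_SPECS)
    P = np.full((K, K), 0.03)
    np.fill_diagonal(P, 0.91)
    return simulate_mixed_type_tracks(
        [dict(s) for s in FOUR_STATE_SPECS],
        P,
        n_tracks,
        track_length,
        TAU,
        np.random.default_rng(seed),
        seed=seed,
    )


def n_state_bm_mixture(n_states, n_tracks, track_length, seed=0):
    """Equal-weight BM mixture with log-spaced D, for accuracy-trend studies."""
    D = np.logspace(np.log10(0.05), np.log10(2.0), n_states)
    P = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(P, 0.95)
    cfg = BrownianSimConfig(
        n_tracks=n_tracks,
        track_length=track_length,
        diffusion_coefficients=D.tolist(),
        transition_matrix=P,
        tau=TAU,
        seed=seed,
    )
    return simulate_bm_tracks(cfg)
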