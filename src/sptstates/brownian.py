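"""Markov-switching multi-state 2D Brownian trajectory simulation.

A hidden state sequence is drawn from a finite Markov chain; conditional on
the state of each step, the 2D displacement is a zero-mean Gaussian whose
per-axis variance is ``2 * D_axis * tau`` (so the 2D mean squared
displacement per frame is ``4 * D * tau`` for isotropic states).  A
motion-blur variant reproduces the camera acquisition process: the true
trajectory is simulated on a grid ``Texp`` times finer, each reported
position is the average of ``Texp`` consecutive fine positions, and
isotropic Gaussian localization noise is added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tracks import GroundTruth, StateSequence, Track, TrackSet

DEFAULT_TAU = 0.02  # s; 50 frames/s camera


@dataclass
class BrownianSimConfig:
    """Settings for a multi-state Brownian dataset.

    ``diffusion_coefficients`` is one entry per state: a scalar ``D`` for an
    isotropic state or an ``(D_x, D_y)`` pair for an anisotropic one, in
    µm²/s.  ``texp`` sub-steps per frame and ``localization_sigma`` (µm)
    switch on the motion-blur observation model when ``texp > 1``.
    """

    n_tracks: int
    track_length: int  # displacements per track
    diffusion_coefficients: Sequence
    transition_matrix: Sequence
    initial_distribution: Sequence | None = None
    tau: float = DEFAULT_TAU
    texp: int = 1
    localization_sigma: float = 0.0
    seed: int | None = None

    def per_axis_d(self) -> np.ndarray:
        d = [np.broadcast_to(np.asarray(x, dtype=float), (2,)) for x in self.diffusion_coefficients]
        return np.stack(d)


def _validate_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    P = _validate_stochastic(P)
    vals, vecs = np.linalg.eig(P.T)
    w = np.real(vecs[:, int(np.argmin(np.abs(vals - 1.0)))])
    w = np.abs(w)
    return w / w.sum()


def simulate_state_sequence(
    transition_matrix,
    initial_distribution,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one state-label series (1-based labels) from a Markov chain."""
    P = _validate_stochastic(transition_matrix)
    if length < 1:
        raise ValueError("length must be >= 1")
    p0 = np.asarray(initial_distribution, dtype=float)
    if p0.shape != (P.shape[0],) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
        raise ValueError("initial distribution must be a simplex of matching size")
    cum = np.cumsum(P, axis=1)
    z = np.empty(length, dtype=np.int64)
    z[0] = rng.choice(P.shape[0], p=p0)
    u = rng.random(length - 1)
    for t in range(1, length):
        z[t] = np.searchsorted(cum[z[t - 1]], u[t - 1], side="right")
    return z + 1


def _simulate_label_block(P, p0, n_tracks, length, rng):
    """Vectorised (n_tracks, length) 0-based label draw from a Markov chain."""
    cum = np.cumsum(P, axis=1)
    z = np.empty((n_tracks, length), dtype=np.int64)
    z[:, 0] = np.searchsorted(np.cumsum(p0), rng.random(n_tracks), side="right")
    u = rng.random((n_tracks, length - 1))
    for t in range(1, length):
        rows = cum[z[:, t - 1]]
        z[:, t] = (u[:, t - 1, None] >= rows).sum(axis=1)
    return z


def simulate_bm_tracks(
    config: BrownianSimConfig, rng: np.random.Generator | None = None
) -> tuple[TrackSet, GroundTruth]:
    """Simulate a standard (no motion blur) Brownian mixture dataset."""
    if config.track_length < 1:
        raise ValueError("track_length must be >= 1")
    if config.tau <= 0:
        raise ValueError("tau must be > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P = _validate_stochastic(config.transition_matrix)
    D = config.per_axis_d()
    if np.any(D <= 0):
        raise ValueError("diffusion coefficients must be > 0")
    p0 = (
        stationary_distribution(P)
        if config.initial_distribution is None
        else np.asarray(config.initial_distribution, dtype=float)
    )
    z = _simulate_label_block(P, p0, config.n_tracks, config.track_length, rng)
    sigma = np.sqrt(2.0 * D * config.tau)  # (K, 2) per-step std per axis
    steps = rng.standard_normal((config.n_tracks, config.track_length, 2)) * sigma[z]
    xy = np.concatenate(
        [np.zeros((config.n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    frames = np.arange(config.track_length + 1)
    tracks = TrackSet(
        [Track(i, frames, xy[i]) for i in range(config.n_tracks)],
        config.tau,
        {"seed": config.seed, "simulator": "bm"},
    )
    gt = GroundTruth(
        StateSequence([z[i] + 1 for i in range(config.n_tracks)], P.shape[0]),
        D,
        P,
    )
    return tracks, gt


def blur_transition_matrix(P: np.ndarray, texp: int) -> np.ndarray:
    """Self-transition-enhanced matrix for the fine (sub-frame) chain.

    Off-diagonal mass is divided by ``texp`` and returned to the diagonal,
    preserving the expected number of state switches per camera frame.
    """
    P = _validate_stochastic(P)
    fine = P / texp
    np.fill_diagonal(fine, 0.0)
    np.fill_diagonal(fine, 1.0 - fine.sum(axis=1))
    return fine


def simulate_motion_blur_tracks(
    config: BrownianSimConfig, rng: np.random.Generator | None = None
) -> tuple[TrackSet, GroundTruth]:
    """Simulate Brownian tracks with exposure averaging and localization noise.

    The state chain and true trajectory run on a grid ``texp`` times finer
    than the camera frame; every reported position is the mean of ``texp``
    consecutive true positions plus isotropic Gaussian noise of standard
    deviation ``localization_sigma``.  Ground-truth labels per camera frame
    are the majority fine-step label (ties break toward the earlier label).
    """
    texp = int(config.texp)
    if texp < 2:
        raise ValueError("motion blur requires texp >= 2")
    if config.localization_sigma < 0:
        raise ValueError("localization_sigma must be >= 0")
    if config.track_length < 1:
        raise ValueError("track_length must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    P = _validate_stochastic(config.transition_matrix)
    K = P.shape[0]
    D = config.per_axis_d()
    if np.any(D <= 0):
        raise ValueError("diffusion coefficients must be > 0")
    fine_P = blur_transition_matrix(P, texp)
    p0 = (
        stationary_distribution(P)
        if config.initial_distribution is None
        else np.asarray(config.initial_distribution, dtype=float)
    )
    n_fine = texp * (config.track_length + 1)
    z_fine = _simulate_label_block(fine_P, p0, config.n_tracks, n_fine, rng)
    sigma = np.sqrt(2.0 * D * (config.tau / texp))
    steps = rng.standard_normal((config.n_tracks, n_fine, 2)) * sigma[z_fine]
    xy_fine = np.cumsum(steps, axis=1)
    # camera position = mean of the texp fine positions inside each exposure
    xy_obs = xy_fine.reshape(config.n_tracks, config.track_length + 1, texp, 2).mean(axis=2)
    if config.localization_sigma > 0:
        xy_obs = xy_obs + rng.normal(
            0.0, config.localization_sigma, size=xy_obs.shape
        )
    # majority label among the fine steps of each output displacement;
    # ties break toward the label seen earliest within the exposure block
    blocks = z_fine[:, texp:].reshape(config.n_tracks, config.track_length, texp)
    onehot = blocks[..., None] == np.arange(K)  # (n, T, texp, K)
    counts = onehot.sum(axis=2)
    first_occ = np.where(counts > 0, np.argmax(onehot, axis=2), texp)
    z_coarse = np.argmax(counts * (texp + 1) - first_occ, axis=2)
    frames = np.arange(config.track_length + 1)
    tracks = TrackSet(
        [Track(i, frames, xy_obs[i]) for i in range(config.n_tracks)],
        config.tau,
        {
            "seed": config.seed,
            "simulator": "bm_motion_blur",
            "texp": texp,
            "localization_sigma": config.localization_sigma,
        },
    )
    gt = GroundTruth(
        StateSequence([z_coarse[i] + 1 for i in range(config.n_tracks)], K), D, P
    )
    return tracks, gt
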