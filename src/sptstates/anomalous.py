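"""Anomalous-diffusion trajectory generators: FBM, CTRW and Lévy walk.

All three families obey MSD ∝ t^alpha with anomalous exponent alpha:
Brownian motion is alpha = 1, subdiffusion alpha < 1, superdiffusion
alpha > 1.

* Fractional Brownian motion (FBM): a Gaussian process with power-law
  correlated increments, Hurst exponent H = alpha/2 and process covariance
  ``E[x(t1) x(t2)] = D_H (t1^{2H} + t2^{2H} - |t1 - t2|^{2H})`` per axis.
  Paths are generated with exact covariance (circulant embedding /
  Davies-Harte, falling back to the Hosking recursion when the embedding is
  not non-negative definite) rather than any Euler approximation.
* Continuous-time random walk (CTRW): power-law waiting times
  ``psi(t) ∝ t^-sigma`` (alpha = sigma - 1 ∈ (0, 1]) separate zero-mean
  Gaussian jumps of fixed variance; the particle is immobile while waiting.
* Lévy walk (LW): flight durations are power-law distributed and the
  particle moves at constant speed v along a uniformly random heading
  during each flight (|dx| / t = v); superdiffusive, alpha ∈ [1, 2]
  via sigma = 3 - alpha.

Power-law sampling uses the inverse CDF with lower cutoff tau and upper
cutoff 1000 tau (recorded in metadata); both walks are reported on the
regular camera frame grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .brownian import DEFAULT_TAU, _simulate_label_block, _validate_stochastic, stationary_distribution
from .tracks import GroundTruth, StateSequence, Track, TrackSet

POWER_LAW_CUTOFF_FRAMES = 1000  # upper waiting-time cutoff, in frames

DIFFUSION_TYPES = ("BM", "FBM", "CTRW", "LW")


@dataclass
class AnomalousSimConfig:
    """Single-state anomalous trajectory settings.

    ``alpha`` is the anomalous exponent; valid ranges are (0, 2) for FBM
    (H = alpha / 2), (0, 1] for CTRW and [1, 2] for LW.  ``scale`` is the
    generalized coefficient D_H for FBM, the per-axis jump standard
    deviation for CTRW (µm) and the speed v (µm/s) for LW.
    """

    diffusion_type: str
    alpha: float
    scale: float
    n_steps: int
    tau: float = DEFAULT_TAU
    seed: int | None = None


# ---------------------------------------------------------------------------
# Fractional Brownian motion


def fgn_increments(
    hurst: float,
    n_steps: int,
    n_paths: int,
    rng: np.random.Generator,
    increment_var: float = 1.0,
) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise, shape (n_paths, n_steps).

    Autocovariance gamma(k) = v/2 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    with gamma(0) = v = ``increment_var``.  Uses Davies-Harte circulant
    embedding; if the embedding eigenvalues are negative (rare, short and
    high-H cases) the O(n^2) Hosking conditional recursion is used instead.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    k = np.arange(n_steps + 1, dtype=float)
    gamma = 0.5 * increment_var * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    if n_steps == 1:
        return rng.standard_normal((n_paths, 1)) * np.sqrt(increment_var)
    circ = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * lam.max():
        return _fgn_hosking(gamma, n_steps, n_paths, rng)
    lam = np.maximum(lam, 0.0)
    m = lam.size  # 2 * n_steps
    z = np.empty((n_paths, m), dtype=complex)
    z[:, 0] = rng.standard_normal(n_paths) * np.sqrt(lam[0])
    z[:, n_steps] = rng.standard_normal(n_paths) * np.sqrt(lam[n_steps])
    a = rng.standard_normal((n_paths, n_steps - 1))
    b = rng.standard_normal((n_paths, n_steps - 1))
    half = np.sqrt(lam[1:n_steps] / 2.0)
    z[:, 1:n_steps] = half * (a + 1j * b)
    z[:, n_steps + 1 :] = np.conj(z[:, n_steps - 1 : 0 : -1])
    x = np.fft.fft(z, axis=1).real / np.sqrt(m)
    return x[:, :n_steps]


def _fgn_hosking(gamma, n_steps, n_paths, rng):
    """Hosking's recursive conditional sampling of fGn (exact, O(n^2))."""
    x = np.empty((n_paths, n_steps))
    x[:, 0] = rng.standard_normal(n_paths) * np.sqrt(gamma[0])
    phi = np.zeros(n_steps)
    v = gamma[0]
    phi_prev = np.zeros(n_steps)
    for t in range(1, n_steps):
        phi_prev[: t - 1] = phi[: t - 1]
        num = gamma[t] - np.dot(phi_prev[: t - 1], gamma[t - 1 : 0 : -1])
        phi_t = num / v
        if t > 1:
            phi[: t - 1] = phi_prev[: t - 1] - phi_t * phi_prev[t - 2 :: -1]
        phi[t - 1] = phi_t
        v *= 1.0 - phi_t * phi_t
        mean = np.einsum("j,ij->i", phi[t - 1 :: -1], x[:, :t])
        x[:, t] = mean + rng.standard_normal(n_paths) * np.sqrt(v)
    return x


def simulate_fbm(
    hurst: float,
    scale: float,
    n_steps: int,
    tau: float = DEFAULT_TAU,
    rng: np.random.Generator | None = None,
    n_paths: int = 1,
) -> np.ndarray:
    """2D FBM positions on the frame grid.

    Each axis is an independent FBM path with process covariance
    ``scale * (t1^{2H} + t2^{2H} - |t1-t2|^{2H})`` (so the per-axis MSD over
    lag t is ``2 * scale * t^{2H}``).  Returns (n_steps + 1, 2) positions
    starting at the origin, or (n_paths, n_steps + 1, 2) when ``n_paths`` > 1.
    """
    rng = np.random.default_rng() if rng is None else rng
    var1 = 2.0 * scale * tau ** (2.0 * hurst)  # per-axis single-step variance
    inc = fgn_increments(hurst, n_steps, 2 * n_paths, rng, increment_var=var1)
    inc = inc.reshape(n_paths, 2, n_steps).transpose(0, 2, 1)
    xy = np.concatenate([np.zeros((n_paths, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    return xy[0] if n_paths == 1 else xy


# ---------------------------------------------------------------------------
# Power-law waiting times (shared by CTRW and LW)


def _power_law_waits(
    sigma_exponent: float,
    n_total: int,
    tau: float,
    rng: np.random.Generator,
    max_wait_frames: float = POWER_LAW_CUTOFF_FRAMES,
) -> np.ndarray:
    """Inverse-CDF draws from psi(t) ∝ t^-sigma on [tau, max_wait_frames * tau]."""
    t_min = tau
    t_max = max_wait_frames * tau
    u = rng.random(n_total)
    if abs(sigma_exponent - 1.0) < 1e-12:
        return t_min * (t_max / t_min) ** u
    a = 1.0 - sigma_exponent
    return (t_min**a + u * (t_max**a - t_min**a)) ** (1.0 / a)


def simulate_ctrw(
    sigma_exponent: float,
    step_std: float,
    n_frames: int,
    tau: float = DEFAULT_TAU,
    rng: np.random.Generator | None = None,
    max_wait_frames: float = POWER_LAW_CUTOFF_FRAMES,
) -> np.ndarray:
    """2D CTRW positions sampled on the regular frame grid.

    ``sigma_exponent`` must give alpha = sigma - 1 in (0, 1]; ``step_std``
    is the per-axis Gaussian jump standard deviation (µm).  Returns
    (n_frames + 1, 2) positions; the particle holds its position between
    jumps.
    """
    alpha = sigma_exponent - 1.0
    if not 0.0 < alpha <= 1.0:
        raise ValueError("CTRW requires alpha = sigma - 1 in (0, 1]")
    if step_std <= 0:
        raise ValueError("step_std must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    horizon = n_frames * tau
    waits = []
    total = 0.0
    while total <= horizon:
        chunk = _power_law_waits(
            sigma_exponent, max(16, n_frames // 4), tau, rng, max_wait_frames
        )
        waits.append(chunk)
        total += float(chunk.sum())
    waits = np.concatenate(waits)
    jump_times = np.cumsum(waits)
    jump_times = jump_times[jump_times <= horizon]
    xy = np.zeros((n_frames + 1, 2))
    if jump_times.size == 0:  # the first wait outlasted the whole movie
        return xy
    jumps = rng.normal(0.0, step_std, size=(jump_times.size, 2))
    pos_after_jump = np.cumsum(jumps, axis=0)
    grid = np.arange(1, n_frames + 1) * tau
    n_done = np.searchsorted(jump_times, grid, side="right")
    xy[1:] = np.where(
        n_done[:, None] > 0, pos_after_jump[np.maximum(n_done - 1, 0)], 0.0
    )
    return xy


def simulate_lw(
    sigma_exponent: float,
    speed: float,
    n_frames: int,
    tau: float = DEFAULT_TAU,
    rng: np.random.Generator | None = None,
    max_wait_frames: float = POWER_LAW_CUTOFF_FRAMES,
) -> np.ndarray:
    """2D Lévy walk positions on the frame grid.

    Flight durations t follow psi(t) ∝ t^-sigma; within each flight the
    particle moves at constant speed ``speed`` along a uniformly random
    heading, so |dx| / t = speed exactly.  With sigma = 3 - alpha this is
    superdiffusive for alpha in [1, 2).  Returns (n_frames + 1, 2).
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    horizon = n_frames * tau
    durations = []
    total = 0.0
    while total <= horizon:
        chunk = _power_law_waits(
            sigma_exponent, max(16, n_frames // 4), tau, rng, max_wait_frames
        )
        durations.append(chunk)
        total += float(chunk.sum())
    durations = np.concatenate(durations)
    ends = np.cumsum(durations)
    n_flights = int(np.searchsorted(ends, horizon, side="right")) + 1
    durations = durations[:n_flights]
    ends = ends[:n_flights]
    starts = ends - durations
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_flights)
    vel = speed * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    # position at flight starts
    start_pos = np.concatenate(
        [np.zeros((1, 2)), np.cumsum(vel[:-1] * durations[:-1, None], axis=0)], axis=0
    )
    grid = np.arange(n_frames + 1) * tau
    idx = np.clip(np.searchsorted(ends, grid, side="right"), 0, n_flights - 1)
    xy = start_pos[idx] + vel[idx] * (grid - starts[idx])[:, None]
    return xy


# ---------------------------------------------------------------------------
# Markov-switching mixtures of diffusion types


def _state_increments(spec: dict, n: int, tau: float, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) displacement draws for a dwell of length n in one state.

    BM and FBM dwells are scaled so the per-axis single-step displacement
    variance is 2 * D * tau, making the state's *apparent* diffusion
    coefficient equal to spec["D"].  FBM correlation is maintained within
    the dwell and resets at state switches.
    """
    kind = spec["type"].upper()
    if kind == "BM":
        return rng.standard_normal((n, 2)) * np.sqrt(2.0 * spec["D"] * tau)
    if kind == "FBM":
        hurst = spec["alpha"] / 2.0
        inc = fgn_increments(hurst, n, 2, rng, increment_var=2.0 * spec["D"] * tau)
        return inc.T.copy()
    if kind == "CTRW":
        xy = simulate_ctrw(spec["sigma_exponent"], spec["step_std"], n, tau, rng)
        return np.diff(xy, axis=0)
    if kind == "LW":
        xy = simulate_lw(spec["sigma_exponent"], spec["speed"], n, tau, rng)
        return np.diff(xy, axis=0)
    raise ValueError(f"unknown diffusion type {spec['type']!r}")


def simulate_mixed_type_tracks(
    state_specs: list[dict],
    transition_matrix,
    n_tracks: int,
    track_length: int,
    tau: float = DEFAULT_TAU,
    rng: np.random.Generator | None = None,
    initial_distribution=None,
    seed: int | None = None,
) -> tuple[TrackSet, GroundTruth]:
    """Markov-switching tracks whose states carry different diffusion types.

    ``state_specs`` holds one dict per state, e.g. ``{"type": "BM",
    "D": 0.9}`` or ``{"type": "FBM", "D": 0.045, "alpha": 0.5}`` (D in
    µm²/s is the apparent per-axis step-variance coefficient).  CTRW and LW
    states are accepted but flagged: a Gaussian-emission state model does
    not describe their displacement statistics, so downstream state
    inference on such data is unreliable.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    P = _validate_stochastic(transition_matrix)
    K = P.shape[0]
    if len(state_specs) != K:
        raise ValueError("need one state spec per transition-matrix row")
    for s in state_specs:
        if s["type"].upper() in ("CTRW", "LW"):
            warnings.warn(
                f"state of type {s['type']}: displacements are non-Gaussian; "
                "Gaussian-emission state inference may mislabel these steps",
                stacklevel=2,
            )
    p0 = (
        stationary_distribution(P)
        if initial_distribution is None
        else np.asarray(initial_distribution, dtype=float)
    )
    z = _simulate_label_block(P, p0, n_tracks, track_length, rng)
    tracks = []
    frames = np.arange(track_length + 1)
    for i in range(n_tracks):
        steps = np.empty((track_length, 2))
        # contiguous dwells: process memory resets at each state switch
        boundaries = np.flatnonzero(np.diff(z[i]) != 0) + 1
        for seg in np.split(np.arange(track_length), boundaries):
            steps[seg] = _state_increments(
                state_specs[z[i, seg[0]]], seg.size, tau, rng
            )
        xy = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)], axis=0)
        tracks.append(Track(i, frames, xy))
    d_app = []
    for s in state_specs:
        if "D" in s:
            d_app.append([s["D"], s["D"]])
        else:  # CTRW/LW: report empirical per-axis step variance / (2 tau)
            d_app.append([np.nan, np.nan])
    d_arr = np.asarray(d_app, dtype=float)
    d_arr = np.where(np.isnan(d_arr), 1.0, d_arr)
    gt = GroundTruth(
        StateSequence([z[i] + 1 for i in range(n_tracks)], K),
        d_arr,
        P,
        diffusion_types=[s["type"].upper() for s in state_specs],
        anomalous_exponents=[s.get("alpha") for s in state_specs],
    )
    return TrackSet(tracks, tau, {"seed": seed, "simulator": "mixed"}), gt


def simulate_single_type(
    config: AnomalousSimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dispatch a single-state path by diffusion type (positions, (n+1, 2))."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    kind = config.diffusion_type.upper()
    if kind == "BM":
        steps = rng.standard_normal((config.n_steps, 2)) * config.scale
        return np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    if kind == "FBM":
        return simulate_fbm(config.alpha / 2.0, config.scale, config.n_steps, config.tau, rng)
    if kind == "CTRW":
        return simulate_ctrw(config.alpha + 1.0, config.scale, config.n_steps, config.tau, rng)
    if kind == "LW":
        return simulate_lw(3.0 - config.alpha, config.scale, config.n_steps, config.tau, rng)
    raise ValueError(f"unknown diffusion type {config.diffusion_type!r}")


def ensemble_msd_exponent(
    paths: np.ndarray,
    tau: float,
    max_lag: int | None = None,
    min_lag: int = 1,
) -> float:
    """Log-log slope of the ensemble MSD versus lag time (alpha estimate).

    ``paths`` is (n_paths, n_frames + 1, 2).  The slope is a least-squares
    fit of log MSD(k tau) against log(k tau) over lags 1..max_lag.
    """
    n_frames = paths.shape[1] - 1
    max_lag = max(2, n_frames // 2) if max_lag is None else max_lag
    lags = np.arange(min_lag, max_lag + 1)
    # ensemble average from the origin (not time-averaged: a time average
    # would report slope 1 for CTRW regardless of alpha)
    msd = np.mean(
        np.sum((paths[:, lags] - paths[:, :1]) ** 2, axis=2), axis=0
    )
    ok = msd > 0  # a CTRW cannot have moved before its first wait elapses
    slope = np.polyfit(np.log(lags[ok] * tau), np.log(msd[ok]), 1)[0]
    return float(slope)
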