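"""Posterior-chain summaries: state count, per-axis D, weights, NHD, ACF.

A posterior chain is reduced to the quantities practitioners report for an
SPT experiment: the modal number of occupied diffusive states, each state's
apparent per-axis diffusion coefficient ``D_axis = Sigma_aa / (2 tau)`` with
posterior spread, its weight fraction of steps, and the transition-matrix
posterior mean.  Evaluation utilities compute the normalized Hamming
distance (NHD) between label sequences under optimal label matching, the
accuracy-versus-track-length curve at a fixed total step budget, and a
posterior-sample autocorrelation diagnostic used to pick the thinning
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hdphmm import HdpHmmConfig, PosteriorChain, PosteriorSample, fit
from .tracks import StateSequence


@dataclass
class IterationStates:
    """Occupied-state summary of one posterior draw, sorted by mean D."""

    iteration: int
    d_x: np.ndarray
    d_y: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    state_ids: np.ndarray  # original 0-based sampler labels

    @property
    def d_mean(self) -> np.ndarray:
        return 0.5 * (self.d_x + self.d_y)


@dataclass
class ChainSummary:
    """Pooled posterior summary after cross-iteration state matching."""

    n_states: int
    d_x: np.ndarray
    d_y: np.ndarray
    d_x_sd: np.ndarray
    d_y_sd: np.ndarray
    weights: np.ndarray
    weights_sd: np.ndarray
    transition_matrix: np.ndarray
    n_iterations_pooled: int
    per_iteration: list[IterationStates] = field(repr=False, default_factory=list)

    @property
    def d_mean(self) -> np.ndarray:
        return 0.5 * (self.d_x + self.d_y)


def iteration_states(sample: PosteriorSample, tau: float) -> IterationStates:
    """Occupied states of one draw: D per axis, weight fraction, mean."""
    occ = sample.occupied_states
    n_total = sample.labels.size
    d_x = sample.covs[occ, 0, 0] / (2.0 * tau)
    d_y = sample.covs[occ, 1, 1] / (2.0 * tau)
    weights = np.array([np.mean(sample.labels == k) for k in occ])
    order = np.argsort(0.5 * (d_x + d_y), kind="stable")
    return IterationStates(
        sample.iteration,
        d_x[order],
        d_y[order],
        weights[order],
        sample.means[occ][order],
        occ[order],
    )


def estimate_num_states(chain: PosteriorChain) -> tuple[int, np.ndarray, bool]:
    """Modal occupied-state count over retained samples.

    Returns ``(mode, per-sample trace, tie_flag)``; ties break toward the
    smaller count (parsimony) and are flagged.
    """
    trace = np.array([s.occupied_count for s in chain.samples])
    if trace.size == 0:
        raise ValueError("empty chain")
    values, counts = np.unique(trace, return_counts=True)
    best = counts.max()
    winners = values[counts == best]
    return int(winners.min()), trace, bool(winners.size > 1)


def match_states_across_iterations(
    summaries: list[IterationStates], reference: IterationStates
) -> list[np.ndarray | None]:
    """Match each iteration's states to reference slots by |log D| distance.

    Returns, per iteration, an index array ``perm`` with ``perm[slot]`` the
    iteration-state index assigned to each reference slot, or ``None`` when
    the occupied-state counts differ (those iterations are reported
    unmatched rather than forced into the reference layout).
    """
    out: list[np.ndarray | None] = []
    ref = np.log(reference.d_mean)
    for it in summaries:
        if it.d_mean.size != ref.size:
            out.append(None)
            continue
        cost = np.abs(np.log(it.d_mean)[None, :] - ref[:, None])
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(ref.size, dtype=np.int64)
        perm[rows] = cols
        out.append(perm)
    return out


def summarize_chain(chain: PosteriorChain, tau: float | None = None) -> ChainSummary:
    """Pool a chain into per-state posterior means and standard deviations.

    Only iterations whose occupied-state count equals the modal count are
    pooled; their states are matched to a common reference by minimal
    total |log D| assignment.  The transition matrix is the posterior mean
    over pooled iterations restricted to the matched states (rows
    renormalised).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    tau = chain.tau if tau is None else tau
    per_it = [iteration_states(s, tau) for s in chain.samples]
    mode_k, _, _ = estimate_num_states(chain)
    modal = [s for s in per_it if s.d_mean.size == mode_k]
    reference = modal[len(modal) // 2]
    perms = match_states_across_iterations(modal, reference)
    dx = np.stack([s.d_x[p] for s, p in zip(modal, perms)])
    dy = np.stack([s.d_y[p] for s, p in zip(modal, perms)])
    w = np.stack([s.weights[p] for s, p in zip(modal, perms)])
    # pooled transition matrix over the matched occupied states
    pis = []
    for s, per in zip(chain.samples, per_it):
        if per.d_mean.size != mode_k:
            continue
        ids = per.state_ids
        sub = s.pi[np.ix_(ids, ids)]
        sub = sub / sub.sum(axis=1, keepdims=True)
        pis.append(sub)
    order = np.argsort(dx.mean(axis=0) + dy.mean(axis=0), kind="stable")
    pi_mean = np.mean(pis, axis=0)[np.ix_(order, order)]
    return ChainSummary(
        n_states=mode_k,
        d_x=dx.mean(axis=0)[order],
        d_y=dy.mean(axis=0)[order],
        d_x_sd=dx.std(axis=0)[order],
        d_y_sd=dy.std(axis=0)[order],
        weights=w.mean(axis=0)[order],
        weights_sd=w.std(axis=0)[order],
        transition_matrix=pi_mean,
        n_iterations_pooled=len(modal),
        per_iteration=per_it,
    )


# ---------------------------------------------------------------------------
# Normalized Hamming distance


@dataclass
class NhdResult:
    nhd: float
    matching: dict  # estimated label -> true label used for the score


def normalized_hamming(z_true: StateSequence, z_est: StateSequence) -> NhdResult:
    """Minimum label-mismatch fraction under optimal label matching.

    The Hamming distance between the concatenated label sequences is
    minimised over one-to-one matchings of estimated to true labels
    (rectangular assignment when the alphabets differ) and normalised by
    the total sequence length, so a global relabelling scores 0 and the
    result never exceeds 1.
    """
    a = z_true.concatenated()
    b = z_est.concatenated()
    if a.size != b.size:
        raise ValueError(f"sequence lengths differ: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty sequences")
    la, ia = np.unique(a, return_inverse=True)
    lb, ib = np.unique(b, return_inverse=True)
    C = np.zeros((lb.size, la.size), dtype=np.int64)
    np.add.at(C, (ib, ia), 1)
    rows, cols = linear_sum_assignment(C, maximize=True)
    agree = C[rows, cols].sum()
    matching = {int(lb[r]): int(la[c]) for r, c in zip(rows, cols)}
    return NhdResult(nhd=1.0 - agree / a.size, matching=matching)


def nhd_trace(chain: PosteriorChain, z_true: StateSequence) -> np.ndarray:
    """NHD of every retained sample's labels against the ground truth."""
    return np.array(
        [normalized_hamming(z_true, chain.state_sequences(s)).nhd for s in chain.samples]
    )


def accuracy_vs_track_length(
    simulate,
    track_lengths: list[int],
    total_steps: int,
    config: HdpHmmConfig,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Label accuracy (1 - NHD) per track length at a fixed step budget.

    ``simulate(n_tracks, track_length, seed)`` must return ``(TrackSet,
    GroundTruth)``; for each length, ``total_steps // length`` tracks are
    simulated, the sampler is run, and the pooled-label accuracy of the
    retained samples is recorded.  Lengths below 2 are skipped.
    """
    out: dict[int, float] = {}
    for length in track_lengths:
        if length < 2:
            continue
        n_tracks = total_steps // length
        seed = int(rng.integers(2**31 - 1))
        tracks, gt = simulate(n_tracks, length, seed)
        chain = fit(tracks, config)
        nhds = nhd_trace(chain, gt.state_sequence)
        out[length] = float(1.0 - nhds.mean())
    return out


def autocorrelation_diagnostic(
    series: np.ndarray, max_lag: int | None = None
) -> dict:
    """Posterior-sample ACF, effective sample size and a suggested thinning.

    The suggested thin is the first lag where |ACF| drops below 0.1.  A
    constant series has no defined ACF and is flagged; fewer than 50 samples
    flags the diagnostic unavailable.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 50:
        return {"available": False, "reason": "need >= 50 samples"}
    if np.ptp(x) == 0:
        return {"available": False, "reason": "constant series: ACF undefined"}
    from statsmodels.tsa.stattools import acf as _acf

    max_lag = min(x.size // 2, 100) if max_lag is None else max_lag
    rho = _acf(x, nlags=max_lag, fft=True)
    below = np.flatnonzero(np.abs(rho[1:]) < 0.1)
    thin = int(below[0] + 1) if below.size else max_lag
    # initial-positive-sequence style ESS with a simple positive-rho cutoff
    pos = rho[1:]
    cut = np.flatnonzero(pos <= 0)
    tail = pos[: cut[0]] if cut.size else pos
    ess = x.size / (1.0 + 2.0 * tail.sum())
    return {
        "available": True,
        "acf": rho,
        "suggested_thin": thin,
        "effective_sample_size": float(ess),
    }
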