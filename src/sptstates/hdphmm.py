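"""Sticky HDP-HMM with multivariate Gaussian emissions, blocked Gibbs sampling.

The model: single-frame displacements y_t are emitted from a latent
Markov chain z_t,

    z_{t+1} | z_t ~ pi(z_t),        y_t | z_t ~ Normal(mu_{z_t}, Sigma_{z_t}),

with a hierarchical Dirichlet process prior over the transition rows,
truncated at L states (weak-limit approximation):

    beta ~ Dir(gamma/L, ..., gamma/L)
    pi_j ~ Dir(a*beta_1, ..., a*beta_j + kappa, ..., a*beta_L)

The sticky mass kappa on the diagonal suppresses spurious rapid state
switching (over-splitting).  Emission parameters carry a conjugate
Normal-inverse-Wishart prior, so every conditional in the Gibbs sweep is
available in closed form.  State sequences are resampled jointly per track
(backward message passing, forward sampling) — the blocked scheme.

The apparent per-axis diffusion coefficient of a state is
``D_axis = Sigma[axis, axis] / (2 * tau)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import invwishart

from .tracks import StateSequence, TrackSet, displacements_from_tracks

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Normal-inverse-Wishart conjugate machinery


@dataclass
class NiwParams:
    """NIW(kappa, mean, dof, scale) over a Gaussian's (mu, Sigma).

    ``Sigma ~ InvWishart(dof, dof * scale)`` and ``mu | Sigma ~
    Normal(mean, Sigma / kappa)``; with this parametrisation the prior
    expectation of Sigma is ``dof * scale / (dof - 3)`` in 2D.
    """

    kappa: float
    mean: np.ndarray
    dof: float
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.scale = np.asarray(self.scale, dtype=float).reshape(2, 2)
        if self.kappa <= 0 or self.dof <= 1:
            raise ValueError("require kappa > 0 and dof > dim - 1")
        if not np.allclose(self.scale, self.scale.T):
            raise ValueError("scale must be symmetric")
        if np.any(np.linalg.eigvalsh(self.scale) <= 0):
            raise ValueError("scale must be positive definite")


def niw_posterior_update(data: np.ndarray, prior: NiwParams) -> NiwParams:
    """Conjugate NIW update for one state's assigned displacements.

    With N points x_n the parameters map to

        kappa' = kappa + N
        kappa' mean' = kappa mean + sum x_n
        dof' = dof + N
        dof' scale' = dof scale + sum x_n x_n^T + kappa mean mean^T
                      - kappa' mean' mean'^T
    """
    X = np.asarray(data, dtype=float).reshape(-1, 2)
    n = X.shape[0]
    if n == 0:
        return NiwParams(prior.kappa, prior.mean.copy(), prior.dof, prior.scale.copy())
    kappa_n = prior.kappa + n
    mean_n = (prior.kappa * prior.mean + X.sum(axis=0)) / kappa_n
    dof_n = prior.dof + n
    scatter = X.T @ X
    scale_n = (
        prior.dof * prior.scale
        + scatter
        + prior.kappa * np.outer(prior.mean, prior.mean)
        - kappa_n * np.outer(mean_n, mean_n)
    ) / dof_n
    scale_n = 0.5 * (scale_n + scale_n.T)
    if np.any(np.linalg.eigvalsh(scale_n) <= 0):  # numerical safety only
        logger.warning("NIW posterior scale not SPD; adding jitter")
        scale_n = scale_n + 1e-12 * np.trace(scale_n) * np.eye(2)
    return NiwParams(kappa_n, mean_n, dof_n, scale_n)


def sample_emission(
    niw: NiwParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu, Sigma) from a NIW: Sigma ~ IW, then mu | Sigma ~ Normal."""
    psi = niw.dof * niw.scale
    try:
        sigma = invwishart.rvs(df=niw.dof, scale=psi, random_state=rng)
    except np.linalg.LinAlgError:
        psi = psi + 1e-10 * np.trace(psi) * np.eye(2)
        sigma = invwishart.rvs(df=niw.dof, scale=psi, random_state=rng)
    sigma = np.atleast_2d(sigma)
    mu = rng.multivariate_normal(niw.mean, sigma / niw.kappa, method="cholesky")
    return mu, sigma


# ---------------------------------------------------------------------------
# Configuration and chain containers


@dataclass
class HdpHmmConfig:
    """Hyperparameters of the sticky HDP-HMM sampler.

    ``sticky_kappa=None`` resolves at fit time to 10% of the total number of
    displacements — strong enough to discourage over-splitting while letting
    the transition counts dominate once states are established.  The NIW
    scale defaults to the empirical covariance of all displacements
    (data-scaled weak prior).  Note the sticky ``sticky_kappa`` and the NIW
    pseudo-count ``niw_kappa`` are unrelated parameters.
    """

    gamma: float = 1.0
    alpha: float = 1.0
    sticky_kappa: float | None = None
    truncation: int = 10
    n_iterations: int = 2000
    burn_in: int = 1000
    thin: int = 10
    niw_kappa: float = 1.0
    niw_mean: tuple[float, float] = (0.0, 0.0)
    niw_dof: float = 4.0
    niw_scale: tuple | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.gamma, self.alpha) <= 0:
            raise ValueError("gamma and alpha must be > 0")
        if self.sticky_kappa is not None and self.sticky_kappa <= 0:
            raise ValueError("sticky_kappa must be > 0")
        if self.truncation < 2:
            raise ValueError("truncation L must be >= 2")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["niw_scale"] is not None:
            d["niw_scale"] = np.asarray(d["niw_scale"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HdpHmmConfig":
        return cls(**d)


@dataclass
class PosteriorSample:
    """One retained Gibbs draw of all latent quantities."""

    iteration: int
    beta: np.ndarray  # (L,)
    pi: np.ndarray  # (L, L)
    means: np.ndarray  # (L, 2)
    covs: np.ndarray  # (L, 2, 2)
    labels: np.ndarray  # (N,) 0-based, concatenated over runs
    occupied_count: int
    log_likelihood: float

    @property
    def occupied_states(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class PosteriorChain:
    """Ordered post-burn-in samples plus the structure needed to interpret them."""

    samples: list[PosteriorSample]
    config: HdpHmmConfig
    tau: float
    run_track_ids: list
    run_lengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        its = [s.iteration for s in self.samples]
        if any(b <= a for a, b in zip(its, its[1:])):
            raise ValueError("iteration indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_steps(self) -> int:
        return int(np.sum(self.run_lengths))

    def state_sequences(self, sample: PosteriorSample) -> StateSequence:
        """Per-run label series (1-based) for one posterior sample."""
        splits = np.cumsum(self.run_lengths)[:-1]
        return StateSequence(
            [z + 1 for z in np.split(sample.labels, splits)],
            self.config.truncation,
        )

    # -- persistence (HDF5) -------------------------------------------------

    def save(self, path: str | Path) -> None:
        import h5py
        import json as _json

        with h5py.File(path, "w") as f:
            f.attrs["config"] = _json.dumps(self.config.to_dict())
            f.attrs["tau"] = self.tau
            f.create_dataset("run_lengths", data=self.run_lengths)
            f.create_dataset(
                "run_track_ids", data=np.array([str(t) for t in self.run_track_ids], dtype="S")
            )
            for i, s in enumerate(self.samples):
                g = f.create_group(f"sample_{i:05d}")
                g.attrs["iteration"] = s.iteration
                g.attrs["occupied_count"] = s.occupied_count
                g.attrs["log_likelihood"] = s.log_likelihood
                for name in ("beta", "pi", "means", "covs", "labels"):
                    g.create_dataset(name, data=getattr(s, name))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorChain":
        import h5py
        import json as _json

        with h5py.File(path, "r") as f:
            config = HdpHmmConfig.from_dict(_json.loads(f.attrs["config"]))
            tau = float(f.attrs["tau"])
            run_lengths = f["run_lengths"][...]
            ids = [t.decode() for t in f["run_track_ids"][...]]
            samples = []
            for key in sorted(k for k in f.keys() if k.startswith("sample_")):
                g = f[key]
                samples.append(
                    PosteriorSample(
                        iteration=int(g.attrs["iteration"]),
                        beta=g["beta"][...],
                        pi=g["pi"][...],
                        means=g["means"][...],
                        covs=g["covs"][...],
                        labels=g["labels"][...],
                        occupied_count=int(g.attrs["occupied_count"]),
                        log_likelihood=float(g.attrs["log_likelihood"]),
                    )
                )
        return cls(samples, config, tau, ids, run_lengths)


# ---------------------------------------------------------------------------
# Conditional samplers (each is an independent Gibbs sweep ingredient)


def _emission_loglik(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Gaussian log density of every displacement under every state, (N, L)."""
    N = X.shape[0]
    L = means.shape[0]
    out = np.empty((N, L))
    for k in range(L):
        s = covs[k]
        det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
        if not np.isfinite(det) or det <= 0:
            raise FloatingPointError(f"state {k}: emission covariance not SPD")
        i00, i11, i01 = s[1, 1] / det, s[0, 0] / det, -s[0, 1] / det
        dx = X[:, 0] - means[k, 0]
        dy = X[:, 1] - means[k, 1]
        quad = dx * dx * i00 + 2.0 * dx * dy * i01 + dy * dy * i11
        out[:, k] = -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad
    return out


def sample_state_sequence(
    displacements: np.ndarray,
    pi: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    rng: np.random.Generator,
    initial_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Jointly draw one track's label sequence from its exact conditional.

    Backward message passing then forward sampling, entirely in log space.
    Returns 0-based labels of length ``len(displacements)``.
    """
    X = np.asarray(displacements, dtype=float).reshape(-1, 2)
    ll = _emission_loglik(X, means, covs)
    L = pi.shape[0]
    beta0 = np.full(L, 1.0 / L) if initial_weights is None else initial_weights
    z = _sample_labels_batch(ll[None, :, :], pi, beta0, rng)
    return z[0]


def _sample_labels_batch(
    ll: np.ndarray, pi: np.ndarray, init: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Blocked label draw for R same-length runs.

    ``ll`` is (R, T, L) per-step emission log likelihood.  Backward messages
    m_t(j) ∝ p(y_{t+1:T} | z_t = j) are propagated in scaled probability
    space — likelihoods are anchored at the per-step maximum log density and
    messages renormalised every step, which is stable for arbitrarily small
    densities — and the forward pass then samples z_1..z_T from the joint
    conditional.
    """
    R, T, L = ll.shape
    lik = np.exp(ll - ll.max(axis=2, keepdims=True))  # per-step anchored, in (0, 1]
    msgs = np.empty((T, R, L))
    msgs[T - 1] = 1.0 / L
    m = msgs[T - 1]
    for t in range(T - 2, -1, -1):
        w = lik[:, t + 1] * m
        m = w @ pi.T
        norm = m.sum(axis=1, keepdims=True)
        if np.any(norm <= 0) or not np.all(np.isfinite(norm)):
            raise FloatingPointError(
                f"non-finite backward message at step {t}: degenerate likelihood"
            )
        m = m / norm
        msgs[t] = m
    z = np.empty((R, T), dtype=np.int64)
    z[:, 0] = _categorical_rows(init[None, :] * lik[:, 0] * msgs[0], rng)
    for t in range(1, T):
        z[:, t] = _categorical_rows(pi[z[:, t - 1]] * lik[:, t] * msgs[t], rng)
    return z


def _categorical_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of unnormalised probabilities."""
    cum = np.cumsum(p, axis=1)
    tot = cum[:, -1]
    if np.any(tot <= 0) or not np.all(np.isfinite(tot)):
        raise FloatingPointError("degenerate state probabilities")
    u = rng.random(p.shape[0]) * tot
    return (u[:, None] >= cum).sum(axis=1)


def sample_transition_rows(
    beta: np.ndarray,
    alpha: float,
    sticky_kappa: float,
    transition_counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw every transition row: pi_j ~ Dir(a beta + kappa e_j + n_j)."""
    counts = np.asarray(transition_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("transition counts must be non-negative")
    L = beta.shape[0]
    conc = alpha * beta[None, :] + sticky_kappa * np.eye(L) + counts
    g = rng.gamma(np.maximum(conc, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def sample_table_counts(
    beta: np.ndarray,
    alpha: float,
    sticky_kappa: float,
    transition_counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Auxiliary Chinese-restaurant 'table' counts m_jk for the beta update.

    Customer i (of the n_jk transitions j->k) opens a new table with
    probability c / (c + i - 1) where c = a beta_k + kappa [j == k]; this is
    exactly the distribution of the number of occupied tables in a CRP.
    """
    counts = np.asarray(transition_counts)
    m = np.zeros(counts.shape, dtype=np.int64)
    for j in range(counts.shape[0]):
        for k in range(counts.shape[1]):
            n = int(counts[j, k])
            if n == 0:
                continue
            c = alpha * beta[k] + (sticky_kappa if j == k else 0.0)
            if c <= 0:
                m[j, k] = 1 if n > 0 else 0
                continue
            p_new = c / (c + np.arange(n))
            m[j, k] = int(np.sum(rng.random(n) < p_new))
    return m


def sample_beta(
    gamma: float,
    table_counts_bar: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Global weights beta ~ Dir(gamma/L + m.bar_{.1}, ..., gamma/L + m.bar_{.L})."""
    mbar = np.asarray(table_counts_bar, dtype=float)
    L = mbar.shape[-1]
    col = mbar.sum(axis=0) if mbar.ndim == 2 else mbar
    g = rng.gamma(gamma / L + col + 1e-12)
    g = np.maximum(g, 1e-300)
    return g / g.sum()


def _override_sticky_tables(
    m: np.ndarray,
    beta: np.ndarray,
    alpha: float,
    sticky_kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Remove the tables attributable to the sticky self-transition bias.

    A fraction of the diagonal tables were created by the kappa mass, not by
    beta; those 'override' tables must not inform the beta posterior.
    """
    mbar = m.astype(float).copy()
    rho = sticky_kappa / (alpha + sticky_kappa)
    for j in range(m.shape[0]):
        if m[j, j] == 0:
            continue
        p = rho / (rho + beta[j] * (1.0 - rho))
        w = rng.binomial(int(m[j, j]), p)
        mbar[j, j] -= w
    return mbar


# ---------------------------------------------------------------------------
# The full blocked Gibbs loop


def _init_labels(X: np.ndarray, L: int) -> np.ndarray:
    """Quantile-bin squared step length into L groups (0-based labels)."""
    r2 = np.einsum("ij,ij->i", X, X)
    order = np.argsort(np.argsort(r2, kind="stable"), kind="stable")
    return (order * L) // X.shape[0]


def _transition_counts(z_groups: list[np.ndarray], L: int) -> np.ndarray:
    counts = np.zeros((L, L), dtype=np.int64)
    for z in z_groups:
        if z.shape[1] < 2:
            continue
        np.add.at(counts, (z[:, :-1].ravel(), z[:, 1:].ravel()), 1)
    return counts


def fit(tracks: TrackSet, config: HdpHmmConfig | None = None) -> PosteriorChain:
    """Run the blocked Gibbs sampler on a track set.

    Each iteration: (1) jointly resample every run's label sequence given
    (pi, emissions); (2) accumulate transition counts and per-state
    sufficient statistics; (3) resample auxiliary table counts, beta, the
    transition rows and each state's (mu, Sigma) — empty states draw from
    the NIW prior.  Every ``thin``-th post-burn-in draw is retained.
    Deterministic under a fixed ``config.seed``.
    """
    config = HdpHmmConfig() if config is None else config
    runs = displacements_from_tracks(tracks)
    if not runs:
        raise ValueError("no displacements: every track needs >= 2 positions")
    rng = np.random.default_rng(config.seed)
    L = config.truncation
    X = np.concatenate([r[1] for r in runs], axis=0)
    N = X.shape[0]
    run_lengths = np.array([r[1].shape[0] for r in runs])
    sticky = (
        0.1 * N if config.sticky_kappa is None else float(config.sticky_kappa)
    )

    # group runs of equal length for vectorised message passing
    groups: dict[int, list[int]] = {}
    for i, ln in enumerate(run_lengths):
        groups.setdefault(int(ln), []).append(i)
    offsets = np.concatenate([[0], np.cumsum(run_lengths)])
    group_index = {
        ln: np.stack([np.arange(offsets[i], offsets[i + 1]) for i in idx])
        for ln, idx in groups.items()
    }

    prior = NiwParams(
        config.niw_kappa,
        np.asarray(config.niw_mean, dtype=float),
        config.niw_dof,
        np.cov(X.T) if config.niw_scale is None else np.asarray(config.niw_scale, float),
    )

    z_flat = _init_labels(X, L)
    beta = np.full(L, 1.0 / L)
    means = np.zeros((L, 2))
    covs = np.tile(np.eye(2), (L, 1, 1))
    pi = np.full((L, L), 1.0 / L)
    pi0 = np.full(L, 1.0 / L)
    start_index = offsets[:-1]  # first displacement of every run

    def resample_parameters(z_flat):
        nonlocal beta, pi, pi0, means, covs
        z_groups = [z_flat[idx] for idx in group_index.values()]
        counts = _transition_counts(z_groups, L)
        # every run's first label is a draw from the shared initial row
        # pi0 ~ Dir(a beta + n0); its table counts feed the beta posterior
        # just like any other restaurant (no sticky bias on pi0)
        counts0 = np.bincount(z_flat[start_index], minlength=L)
        m = sample_table_counts(beta, config.alpha, sticky, counts, rng)
        m0 = sample_table_counts(beta, config.alpha, 0.0, counts0[None, :], rng)
        mbar = _override_sticky_tables(m, beta, config.alpha, sticky, rng)
        beta = sample_beta(config.gamma, mbar.sum(axis=0) + m0[0], rng)
        pi = sample_transition_rows(beta, config.alpha, sticky, counts, rng)
        g0 = np.maximum(rng.gamma(np.maximum(config.alpha * beta + counts0, 1e-12)), 1e-300)
        pi0 = g0 / g0.sum()
        for k in range(L):
            post = niw_posterior_update(X[z_flat == k], prior)
            means[k], covs[k] = sample_emission(post, rng)

    resample_parameters(z_flat)

    samples: list[PosteriorSample] = []
    occupied_trace = np.empty(config.n_iterations, dtype=np.int64)
    for it in range(config.n_iterations):
        ll_all = _emission_loglik(X, means, covs)
        if not np.all(np.isfinite(ll_all)):
            raise FloatingPointError(f"divergence at iteration {it}: non-finite likelihood")
        z_flat = np.empty(N, dtype=np.int64)
        for ln, idx in group_index.items():
            z_g = _sample_labels_batch(
                ll_all[idx.ravel()].reshape(idx.shape[0], ln, L), pi, pi0, rng
            )
            z_flat[idx.ravel()] = z_g.ravel()
        resample_parameters(z_flat)
        occ = int(np.unique(z_flat).size)
        occupied_trace[it] = occ
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            loglik = float(ll_all[np.arange(N), z_flat].sum())
            samples.append(
                PosteriorSample(
                    iteration=it,
                    beta=beta.copy(),
                    pi=pi.copy(),
                    means=means.copy(),
                    covs=covs.copy(),
                    labels=z_flat.copy(),
                    occupied_count=occ,
                    log_likelihood=loglik,
                )
            )
        if (it + 1) % 100 == 0:
            logger.info("iteration %d: occupied states = %d", it + 1, occ)

    return PosteriorChain(
        samples,
        config,
        tracks.tau,
        [r[0] for r in runs],
        run_lengths,
        diagnostics={"occupied_trace": occupied_trace, "sticky_kappa": sticky},
    )
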