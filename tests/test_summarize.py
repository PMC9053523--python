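"""Chain summaries, state matching, NHD and the ACF diagnostic."""

import itertools

import numpy as np
import pytest

from sptstates import (
    StateSequence,
    autocorrelation_diagnostic,
    estimate_num_states,
    match_states_across_iterations,
    normalized_hamming,
    summarize_chain,
)
from sptstates.hdphmm import HdpHmmConfig, PosteriorChain, PosteriorSample
from sptstates.summarize import IterationStates, iteration_states

TAU = 0.02


def _sample(iteration, covs_diag, labels, L=4):
    """Build a synthetic PosteriorSample with given per-state variances."""
    covs = np.tile(np.eye(2) * 1e-3, (L, 1, 1))
    for k, v in covs_diag.items():
        covs[k] = np.diag(v)
    labels = np.asarray(labels)
    return PosteriorSample(
        iteration=iteration,
        beta=np.full(L, 1.0 / L),
        pi=np.full((L, L), 1.0 / L),
        means=np.zeros((L, 2)),
        covs=covs,
        labels=labels,
        occupied_count=np.unique(labels).size,
        log_likelihood=0.0,
    )


def _chain(samples):
    n = samples[0].labels.size if samples else 4
    return PosteriorChain(
        samples,
        HdpHmmConfig(n_iterations=1000, burn_in=0, thin=1, truncation=4),
        TAU,
        ["t0"],
        np.array([n]),
    )


class TestIterationSummary:
    def test_d_from_sigma_diagonal(self):
        # sigma = diag(0.0054) µm², tau = 0.02 s -> D = 0.135 µm²/s
        s = _sample(0, {0: (0.0054, 0.0054)}, np.zeros(10, dtype=int))
        it = iteration_states(s, TAU)
        np.testing.assert_allclose(it.d_x, [0.135])
        np.testing.assert_allclose(it.d_y, [0.135])

    def test_single_state_weight_is_one(self):
        s = _sample(0, {0: (0.01, 0.01)}, np.zeros(7, dtype=int))
        it = iteration_states(s, TAU)
        np.testing.assert_allclose(it.weights, [1.0])

    def test_states_sorted_ascending_by_d(self):
        s = _sample(0, {1: (0.1, 0.1), 2: (0.001, 0.001)}, np.array([1, 2, 1, 2]))
        it = iteration_states(s, TAU)
        assert it.d_mean[0] < it.d_mean[1]


class TestEstimateNumStates:
    def test_constant_trace(self):
        samples = [_sample(i, {0: (0.01, 0.01), 1: (0.1, 0.1)}, np.array([0, 1]))
                   for i in range(4)]
        k, trace, tie = estimate_num_states(_chain(samples))
        assert k == 2 and not tie and np.all(trace == 2)

    def test_mode_of_mixed_trace(self):
        samples = [
            _sample(0, {0: (0.01, 0.01), 1: (0.1, 0.1)}, np.array([0, 1])),
            _sample(1, {0: (0.01, 0.01), 1: (0.1, 0.1)}, np.array([0, 1])),
            _sample(2, {0: (0.01, 0.01), 1: (0.1, 0.1), 2: (1, 1)}, np.array([0, 1, 2])),
            _sample(3, {0: (0.01, 0.01), 1: (0.1, 0.1)}, np.array([0, 1])),
        ]
        k, _, _ = estimate_num_states(_chain(samples))
        assert k == 2

    def test_tie_breaks_toward_fewer_states_and_flags(self):
        samples = [
            _sample(0, {0: (0.01, 0.01)}, np.array([0, 0])),
            _sample(1, {0: (0.01, 0.01), 1: (0.1, 0.1)}, np.array([0, 1])),
        ]
        k, _, tie = estimate_num_states(_chain(samples))
        assert k == 1 and tie


class TestStateMatching:
    def _it(self, ds):
        ds = np.asarray(ds, dtype=float)
        return IterationStates(0, ds, ds, np.full(ds.size, 1 / ds.size),
                               np.zeros((ds.size, 2)), np.arange(ds.size))

    def test_identity(self):
        ref = self._it([0.1, 1.0])
        perms = match_states_across_iterations([self._it([0.1, 1.0])], ref)
        np.testing.assert_array_equal(perms[0], [0, 1])

    def test_count_mismatch_reported_unmatched(self):
        ref = self._it([0.1, 1.0])
        perms = match_states_across_iterations([self._it([0.1, 0.5, 1.0])], ref)
        assert perms[0] is None

    def test_matches_brute_force_over_permutations(self, rng):
        ref_d = np.array([0.05, 0.4, 2.0])
        ref = self._it(ref_d)
        for _ in range(20):
            perm = rng.permutation(3)
            noisy = ref_d[perm] * np.exp(rng.normal(0, 0.05, 3))
            it = self._it(np.sort(noisy))  # summaries arrive sorted
            got = match_states_across_iterations([it], ref)[0]
            best = min(
                itertools.permutations(range(3)),
                key=lambda p: sum(
                    abs(np.log(it.d_mean[p[i]]) - np.log(ref_d[i])) for i in range(3)
                ),
            )
            np.testing.assert_array_equal(got, best)


class TestNormalizedHamming:
    def test_identical_sequences_zero(self):
        z = StateSequence([np.array([1, 2, 1, 1])], 2)
        assert normalized_hamming(z, z).nhd == 0.0

    def test_global_permutation_scores_zero(self):
        a = StateSequence([np.array([1, 2, 2, 1, 3])], 3)
        b = StateSequence([np.array([3, 1, 1, 3, 2])], 3)
        assert normalized_hamming(a, b).nhd == 0.0

    def test_worst_case_binary(self):
        # under the best matching every position still disagrees
        a = StateSequence([np.array([1, 1, 2, 2])], 2)
        b = StateSequence([np.array([2, 1, 1, 2])], 2)
        # best matching keeps 2/4 agreement -> NHD 0.5; truly all-different
        # requires a 1-state estimate against a 2-state truth
        c = StateSequence([np.array([1, 1, 1, 1])], 1)
        d = StateSequence([np.array([1, 2, 1, 2])], 2)
        assert normalized_hamming(a, b).nhd == 0.5
        assert normalized_hamming(d, c).nhd == 0.5

    def test_permutation_invariance_property(self, rng):
        for _ in range(10):
            z1 = rng.integers(1, 4, size=60)
            z2 = rng.integers(1, 4, size=60)
            base = normalized_hamming(
                StateSequence([z1], 3), StateSequence([z2], 3)
            ).nhd
            perm = rng.permutation(3) + 1
            z2p = perm[z2 - 1]
            again = normalized_hamming(
                StateSequence([z1], 3), StateSequence([z2p], 3)
            ).nhd
            assert base == pytest.approx(again)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            normalized_hamming(
                StateSequence([np.array([1, 1])], 1),
                StateSequence([np.array([1])], 1),
            )


class TestPooledSummary:
    def test_weights_sum_to_one_and_matching_pools_correctly(self):
        samples = []
        for i in range(6):
            # swap sampler label identities on odd iterations
            if i % 2 == 0:
                covs, labels = {0: (0.004, 0.004), 1: (0.08, 0.08)}, [0, 0, 1, 1]
            else:
                covs, labels = {1: (0.004, 0.004), 0: (0.08, 0.08)}, [1, 1, 0, 0]
            samples.append(_sample(i, covs, np.array(labels * 5)))
        s = summarize_chain(_chain(samples))
        assert s.n_states == 2
        np.testing.assert_allclose(s.weights.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(s.d_mean, [0.1, 2.0])
        np.testing.assert_allclose(s.d_x_sd, 0.0, atol=1e-12)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_chain(_chain([]))


class TestAcfDiagnostic:
    def test_white_noise_thin_one(self, rng):
        out = autocorrelation_diagnostic(rng.standard_normal(5000))
        assert out["available"] and out["suggested_thin"] == 1

    def test_ar1_acf_matches_closed_form(self, rng):
        phi = 0.9
        x = np.empty(10_000)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(10_000)
        for t in range(1, x.size):
            x[t] = phi * x[t - 1] + eps[t]
        out = autocorrelation_diagnostic(x)
        assert abs(out["acf"][1] - phi) < 0.03

    def test_constant_series_flagged(self):
        out = autocorrelation_diagnostic(np.ones(100))
        assert not out["available"]

    def test_too_few_samples_flagged(self, rng):
        assert not autocorrelation_diagnostic(rng.standard_normal(10))["available"]
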