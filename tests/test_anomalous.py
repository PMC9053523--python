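"""FBM / CTRW / LW generators: covariance, scaling exponents, invariants."""

import numpy as np
import pytest
from scipy import stats

from sptstates import (
    ensemble_msd_exponent,
    fgn_increments,
    simulate_ctrw,
    simulate_fbm,
    simulate_lw,
    simulate_mixed_type_tracks,
)
from sptstates.anomalous import _power_law_waits

TAU = 0.02


class TestFbm:
    def test_hurst_half_is_uncorrelated(self, rng):
        inc = fgn_increments(0.5, 10_000, 1, rng)[0]
        r = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(r) < 0.02

    def test_invalid_hurst_rejected(self, rng):
        for h in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError, match="Hurst"):
                fgn_increments(h, 10, 1, rng)

    def test_process_covariance_closed_form(self, rng):
        # E[x(t1) x(t2)] = D_H (t1^2H + t2^2H - |t1-t2|^2H) at H = 0.25
        H, DH = 0.25, 1.0
        paths = simulate_fbm(H, DH, 20, TAU, rng, n_paths=10_000)
        t1, t2 = 5 * TAU, 10 * TAU
        emp = np.mean(paths[:, 5, 0] * paths[:, 10, 0])
        theo = DH * (t1 ** (2 * H) + t2 ** (2 * H) - abs(t1 - t2) ** (2 * H))
        # Monte-Carlo CI: sd of the product / sqrt(n), ~4 sigma slack
        assert abs(emp - theo) < 4 * theo / np.sqrt(10_000) * 2

    def test_msd_slope_is_two_h(self, rng):
        paths = simulate_fbm(0.25, 1.0, 100, TAU, rng, n_paths=10_000)
        assert abs(ensemble_msd_exponent(paths, TAU) - 0.5) < 0.05

    @pytest.mark.parametrize("H,sign", [(0.75, 1), (0.25, -1)])
    def test_lag1_autocorrelation_sign_matches_hurst(self, H, sign, rng):
        inc = fgn_increments(H, 5_000, 4, rng)
        r = np.mean(
            [np.corrcoef(row[:-1], row[1:])[0, 1] for row in inc]
        )
        assert np.sign(r) == sign

    def test_hosking_fallback_matches_embedding_covariance(self, rng):
        from sptstates.anomalous import _fgn_hosking

        H, n = 0.3, 30
        k = np.arange(n + 1, dtype=float)
        gamma = 0.5 * (
            np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H)
        )
        x = _fgn_hosking(gamma, n, 40_000, rng)
        emp = np.mean(x[:, 0] * x[:, 5])
        assert abs(emp - gamma[5]) < 0.01


class TestPowerLawWaits:
    def test_tail_index_hill_estimator(self, rng):
        # psi(t) ~ t^-sigma: Hill estimate of the tail index on the upper
        # order statistics should recover sigma - 1 within 10%
        sigma = 1.5
        w = _power_law_waits(sigma, 200_000, 1.0, rng, max_wait_frames=1e9)
        w = np.sort(w)[-20_000:]
        hill = 1.0 / np.mean(np.log(w / w[0]))
        assert abs(hill - (sigma - 1.0)) < 0.1 * (sigma - 1.0)

    def test_waits_respect_cutoffs(self, rng):
        w = _power_law_waits(1.7, 10_000, 0.02, rng, max_wait_frames=1000)
        assert w.min() >= 0.02 and w.max() <= 0.02 * 1000


class TestCtrw:
    def test_alpha_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha"):
            simulate_ctrw(2.5, 1.0, 10, TAU, rng)  # alpha = 1.5 > 1

    def test_subdiffusive_scaling_alpha_half(self, rng):
        # fractional regime needs lags well above the waiting-time floor and
        # an upper cutoff far beyond the fit window
        paths = np.stack(
            [
                simulate_ctrw(1.5, 1.0, 2000, 1.0, rng, max_wait_frames=1e5)
                for _ in range(1500)
            ]
        )
        slope = ensemble_msd_exponent(paths, 1.0, min_lag=100, max_lag=1600)
        assert abs(slope - 0.5) < 0.1

    def test_diffusive_limit_alpha_one(self, rng):
        # with sigma = 2 the count process has log corrections; beyond the
        # default upper cutoff the walk is asymptotically diffusive
        paths = np.stack(
            [simulate_ctrw(2.0, 1.0, 6000, 1.0, rng) for _ in range(600)]
        )
        slope = ensemble_msd_exponent(paths, 1.0, min_lag=2000, max_lag=5900)
        assert abs(slope - 1.0) < 0.1

    def test_particle_immobile_between_jumps(self, rng):
        xy = simulate_ctrw(1.3, 1.0, 500, TAU, rng)
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        assert np.mean(d == 0.0) > 0.3  # waits >= tau force many still frames


class TestLw:
    def test_constant_flight_speed(self, rng):
        # reconstruct per-frame speeds: inside a flight |dx|/tau = v exactly
        v = 2.0
        xy = simulate_lw(1.5, v, 2000, TAU, rng)
        speeds = np.linalg.norm(np.diff(xy, axis=0), axis=1) / TAU
        frac_at_v = np.mean(np.abs(speeds - v) < 1e-9)
        assert frac_at_v > 0.9  # all frames except flight-boundary frames

    def test_superdiffusive(self, rng):
        paths = np.stack([simulate_lw(1.5, 1.0, 200, 1.0, rng) for _ in range(2000)])
        assert ensemble_msd_exponent(paths, 1.0) > 1.0

    def test_headings_uniform_rayleigh(self, rng):
        # Rayleigh test of heading uniformity on ~10^4 flights; one heading
        # per flight (per-frame headings repeat within a flight)
        headings = []
        for _ in range(50):
            xy = simulate_lw(1.5, 1.0, 2000, TAU, rng)
            d = np.diff(xy, axis=0)
            keep = np.linalg.norm(d, axis=1) > 0
            th = np.arctan2(d[keep, 1], d[keep, 0])
            th = th[np.concatenate([[True], np.abs(np.diff(th)) > 1e-12])]
            headings.append(th)
        theta = np.concatenate(headings)[:10_000]
        n = theta.size
        R = np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / n
        p = np.exp(-n * R**2)  # Rayleigh-test approximation
        assert p > 0.01

    def test_nonpositive_speed_rejected(self, rng):
        with pytest.raises(ValueError, match="speed"):
            simulate_lw(1.5, 0.0, 10, TAU, rng)


class TestMixedTypeTracks:
    def test_two_state_bm_fbm_mixture_step_variances(self, rng):
        specs = [
            {"type": "FBM", "D": 0.045, "alpha": 0.5},
            {"type": "BM", "D": 0.90},
        ]
        P = [[0.95, 0.05], [0.05, 0.95]]
        tracks, gt = simulate_mixed_type_tracks(specs, P, 200, 100, TAU, rng)
        steps = np.concatenate([np.diff(t.xy, axis=0) for t in tracks])
        z = gt.state_sequence.concatenated()
        # apparent D = per-axis step variance / (2 tau) per state
        d1 = steps[z == 1].var(axis=0).mean() / (2 * TAU)
        d2 = steps[z == 2].var(axis=0).mean() / (2 * TAU)
        np.testing.assert_allclose(d1, 0.045, rtol=0.1)
        np.testing.assert_allclose(d2, 0.90, rtol=0.1)
        assert gt.diffusion_types == ["FBM", "BM"]

    def test_single_state_mixture_reduces_to_pure_bm(self, rng):
        tracks, _ = simulate_mixed_type_tracks(
            [{"type": "BM", "D": 1.0}], [[1.0]], 30, 400, TAU, rng
        )
        steps = np.concatenate([np.diff(t.xy, axis=0) for t in tracks])
        # distribution equality with BM: variance and normality
        np.testing.assert_allclose(steps.var(axis=0), 2 * 1.0 * TAU, rtol=0.05)
        assert stats.normaltest(steps[:, 0]).pvalue > 0.01

    def test_ctrw_state_flagged(self, rng):
        with pytest.warns(UserWarning, match="non-Gaussian"):
            simulate_mixed_type_tracks(
                [{"type": "CTRW", "sigma_exponent": 1.5, "step_std": 0.05}],
                [[1.0]],
                2,
                50,
                TAU,
                rng,
            )

    def test_fbm_memory_within_dwell(self, rng):
        # a persistent (H > 0.5) FBM state must show positive lag-1
        # increment correlation inside dwells
        tracks, gt = simulate_mixed_type_tracks(
            [{"type": "FBM", "D": 1.0, "alpha": 1.6}], [[1.0]], 50, 200, TAU, rng
        )
        cors = []
        for t in tracks:
            d = np.diff(t.xy, axis=0)
            cors.append(np.corrcoef(d[:-1, 0], d[1:, 0])[0, 1])
        assert np.mean(cors) > 0.1

    def test_reproducible_under_seed(self):
        specs = [{"type": "FBM", "D": 0.5, "alpha": 0.7}]
        a, _ = simulate_mixed_type_tracks(specs, [[1.0]], 3, 50, TAU, seed=42)
        b, _ = simulate_mixed_type_tracks(specs, [[1.0]], 3, 50, TAU, seed=42)
        np.testing.assert_array_equal(a.tracks[2].xy, b.tracks[2].xy)


@pytest.mark.parametrize(
    "make,alpha",
    [
        (lambda rng: simulate_fbm(0.35, 1.0, 100, 1.0, rng, n_paths=4000), 0.7),
        (lambda rng: simulate_fbm(0.65, 1.0, 100, 1.0, rng, n_paths=4000), 1.3),
    ],
)
def test_generator_recovers_target_alpha(make, alpha, rng):
    paths = make(rng)
    assert abs(ensemble_msd_exponent(paths, 1.0) - alpha) < 0.1
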