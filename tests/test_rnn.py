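"""The LSTM diffusion-type classifier and anomalous-exponent regressor.

Training here uses deliberately small corpora and few epochs: enough signal
to verify learning happens and the contracts hold, not to reach the
accuracy of the full-scale networks.
"""

import numpy as np
import pytest

import sptstates.rnn as rnn
from sptstates.rnn import (
    CLASS_NAMES,
    ClassifierSpec,
    TrainedModel,
    classify_segments,
    make_classification_corpus,
    make_fbm_regression_corpus,
    regress_alpha,
    train_alpha_regressor,
    train_classifier,
)
from sptstates.segments import Segment, SegmentBatch


@pytest.fixture(scope="module")
def small_classifier():
    rng = np.random.default_rng(7)
    X, y = make_classification_corpus(2000, 20, rng)
    spec = ClassifierSpec(
        input_steps=20, task="classify", max_epochs=15, seed=7, batch_size=128
    )
    return train_classifier(spec, X, y)


class TestGradients:
    def test_bptt_matches_numerical_gradient(self):
        old = rnn.DTYPE
        rnn.DTYPE = np.float64
        try:
            spec = ClassifierSpec(input_steps=20, hidden=(5, 4), task="regress", seed=3)
            params = rnn.init_params(spec)
            rng = np.random.default_rng(0)
            X = rng.standard_normal((3, 8, 2))
            y = np.array([0.5, 1.2, 0.8])

            def loss():
                out = rnn._forward(params, X)[:, 0]
                return float(np.mean((out - y) ** 2))

            out, caches = rnn._forward(params, X, want_cache=True)
            dout = (2.0 * (out[:, 0] - y) / 3)[:, None]
            grads = rnn._backward(params, caches, dout)
            flat_p = dict(rnn._flatten(params))
            flat_g = dict(rnn._flatten(grads))
            check_rng = np.random.default_rng(1)
            for k, v in flat_p.items():
                for i in check_rng.choice(v.size, size=min(4, v.size), replace=False):
                    ix = np.unravel_index(i, v.shape)
                    eps, old_v = 1e-6, v[ix]
                    v[ix] = old_v + eps
                    lp = loss()
                    v[ix] = old_v - eps
                    lm = loss()
                    v[ix] = old_v
                    num = (lp - lm) / (2 * eps)
                    ana = flat_g[k][ix]
                    assert abs(num - ana) <= 1e-4 * (abs(num) + abs(ana)) + 1e-9
        finally:
            rnn.DTYPE = old


class TestClassifierTraining:
    def test_accuracy_well_above_chance(self, small_classifier):
        assert small_classifier.holdout_metric > 0.5  # chance = 0.25

    def test_bm_recall_dominates(self, small_classifier):
        cm = small_classifier.confusion_matrix
        bm = list(CLASS_NAMES).index("BM")
        assert cm[bm, bm] >= cm[bm].sum() * 0.5

    def test_label_shuffle_gives_chance_level(self):
        rng = np.random.default_rng(11)
        X, y = make_classification_corpus(150, 20, rng)
        y_shuf = rng.permutation(y)
        # keep balance intact (permutation preserves counts)
        spec = ClassifierSpec(
            input_steps=20, task="classify", max_epochs=3, seed=11, batch_size=128
        )
        model = train_classifier(spec, X, y_shuf)
        assert abs(model.holdout_metric - 0.25) < 0.12

    def test_imbalanced_corpus_refused(self, rng):
        X = rng.normal(size=(120, 21, 2)).cumsum(axis=1)
        y = np.repeat([0, 1, 2, 3], [60, 20, 20, 20])
        spec = ClassifierSpec(input_steps=20, task="classify", seed=0)
        with pytest.raises(ValueError, match="imbalance"):
            train_classifier(spec, X, y)

    def test_save_load_round_trip(self, small_classifier, tmp_path):
        small_classifier.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 21, 2)).cumsum(axis=1)
        np.testing.assert_array_equal(
            rnn.predict(back, X), rnn.predict(small_classifier, X)
        )
        assert back.spec.hidden == small_classifier.spec.hidden


class TestSegmentInference:
    def _batch(self, n_steps, n_segments, rng):
        segs = [
            Segment(i, 1, rng.normal(size=(n_steps + 1, 2)).cumsum(axis=0))
            for i in range(n_segments)
        ]
        return SegmentBatch(segs)

    def test_probabilities_sum_to_one(self, small_classifier, rng):
        probs = classify_segments(small_classifier, self._batch(20, 5, rng))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_segments_identical_outputs(self, small_classifier, rng):
        xy = rng.normal(size=(21, 2)).cumsum(axis=0)
        batch = SegmentBatch([Segment(0, 1, xy), Segment(1, 1, xy.copy())])
        probs = classify_segments(small_classifier, batch)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_too_short_segment_rejected_as_nan(self, small_classifier, rng):
        probs = classify_segments(small_classifier, self._batch(10, 2, rng))
        assert np.all(np.isnan(probs))

    def test_long_segments_windowed(self, small_classifier, rng):
        # 50 steps with a 20-step network -> two windows, remainder dropped
        batch = self._batch(50, 1, rng)
        probs = classify_segments(small_classifier, batch)
        w1 = batch.segments[0].xy[:21]
        w2 = batch.segments[0].xy[20:41]
        expected = rnn.predict(small_classifier, np.stack([w1, w2])).mean(axis=0)
        np.testing.assert_allclose(probs[0], expected, atol=1e-6)

    def test_rotation_consistency(self, small_classifier, rng):
        # normalization keeps one global scale, so a rigid rotation should
        # barely move the class probabilities
        xy = rng.normal(size=(21, 2)).cumsum(axis=0)
        c, s = np.cos(0.8), np.sin(0.8)
        rot = xy @ np.array([[c, -s], [s, c]]).T
        batch = SegmentBatch([Segment(0, 1, xy), Segment(1, 1, rot)])
        probs = classify_segments(small_classifier, batch)
        assert np.max(np.abs(probs[0] - probs[1])) < 0.35


@pytest.fixture(scope="module")
def small_regressor():
    rng = np.random.default_rng(23)
    X, a = make_fbm_regression_corpus(3000, 20, rng)
    spec = ClassifierSpec(
        input_steps=20, task="regress", max_epochs=10, seed=23, batch_size=128
    )
    return train_alpha_regressor(spec, X, a)


class TestRegression:

    def test_learns_subdiffusive_vs_superdiffusive(self, small_regressor):
        rng = np.random.default_rng(9)
        X_lo, _ = make_fbm_regression_corpus(300, 20, rng, alpha_range=(0.3, 0.3))
        X_hi, _ = make_fbm_regression_corpus(300, 20, rng, alpha_range=(1.7, 1.7))
        lo = rnn.predict(small_regressor, X_lo)[:, 0].mean()
        hi = rnn.predict(small_regressor, X_hi)[:, 0].mean()
        assert lo < 1.0 < hi

    def test_estimates_clipped_to_valid_range(self, small_regressor, rng):
        batch = SegmentBatch(
            [Segment(0, 1, rng.normal(size=(21, 2)).cumsum(axis=0)) for _ in range(3)]
        )
        est, per_state = regress_alpha(small_regressor, batch, "FBM")
        ok = est[np.isfinite(est)]
        assert np.all((ok >= 0.05) & (ok <= 1.95))

    def test_bm_has_no_regression_model(self, small_regressor, rng):
        with pytest.raises(ValueError, match="BM"):
            regress_alpha(small_regressor, SegmentBatch([]), "BM")


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"input_steps": 10}, {"hidden": (0, 5)}, {"task": "segment"}],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)

    def test_training_deterministic_under_seed(self):
        rng1 = np.random.default_rng(3)
        X, a = make_fbm_regression_corpus(200, 20, rng1)
        spec = ClassifierSpec(input_steps=20, task="regress", max_epochs=2, seed=5)
        m1 = train_alpha_regressor(spec, X, a)
        m2 = train_alpha_regressor(spec, X, a)
        for (k1, v1), (k2, v2) in zip(
            sorted(rnn._flatten(m1.params)), sorted(rnn._flatten(m2.params))
        ):
            np.testing.assert_array_equal(v1, v2)


class TestEndToEndTypeCalls:
    """Full pipeline on the BM + subdiffusive-FBM mixture: the slow state
    should be called FBM and the fast state BM, across seeds."""

    @pytest.mark.parametrize("seed", [9, 19, 29])
    def test_state_type_calls_match_truth(self, small_classifier, seed):
        from sptstates import (
            HdpHmmConfig, estimate_num_states, extract_segments, fit,
            state_type_probability, summarize_chain,
        )
        from sptstates import regimes
        from sptstates.pipeline import _representative_sample
        from sptstates.segments import SegmentBatch

        tracks, _ = regimes.bm_fbm_mixture(200, 100, seed=seed)
        chain = fit(
            tracks, HdpHmmConfig(n_iterations=500, burn_in=250, thin=10, seed=seed)
        )
        k, _, _ = estimate_num_states(chain)
        assert k == 2
        summary = summarize_chain(chain)
        labels = chain.state_sequences(_representative_sample(chain, k))
        batch = extract_segments(tracks, labels, min_length=20)
        probs = classify_segments(small_classifier, batch)
        calls = state_type_probability(batch, probs, CLASS_NAMES)
        # identify slow/fast sampler labels via the per-iteration summary
        rep = _representative_sample(chain, k)
        from sptstates.summarize import iteration_states

        states = iteration_states(rep, tracks.tau)
        slow_label, fast_label = int(states.state_ids[0]) + 1, int(states.state_ids[-1]) + 1
        assert calls[slow_label]["top_type"] == "FBM"
        assert calls[fast_label]["top_type"] == "BM"
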