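"""Estimate the anomalous exponent of FBM segments with the LSTM regressor.

Trains the scalar-output network on simulated 40-step FBM tracks with alpha
drawn uniformly from (0.1, 1.9), then evaluates it on held-out tracks
generated at alpha = 0.5 and alpha = 1.0.  The printed means should land
near the true exponents; the spread reflects how little information a
single 40-step track carries about alpha.  (This uses a reduced corpus; the
full-scale run lives in scripts/acceptance.py.)
"""

import numpy as np

import sptstates.rnn as rnn

rng = np.random.default_rng(21)
X, a = rnn.make_fbm_regression_corpus(8000, 40, rng)
spec = rnn.ClassifierSpec(input_steps=40, task="regress", max_epochs=15, seed=2,
                          batch_size=256, patience=4)
model = rnn.train_alpha_regressor(spec, X, a)
print(f"held-out MAE over alpha in (0.1, 1.9): {model.holdout_metric:.3f}")

for alpha in (0.5, 1.0):
    Xe, _ = rnn.make_fbm_regression_corpus(400, 40, rng, alpha_range=(alpha, alpha))
    est = rnn.predict(model, Xe)[:, 0]
    print(f"true alpha = {alpha}: mean estimate {est.mean():.3f} +- {est.std():.3f}")
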