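"""End to end: state inference, segmentation and diffusion-type calls.

Simulates the BM + subdiffusive-FBM mixture (apparent D = 0.045 and
0.90 µm²/s, FBM alpha = 0.5), infers the states with the HDP-HMM, slices
the tracks into same-state segments (>= 20 steps here), and classifies each
state's diffusion type with a quickly trained LSTM network.  Expect the
slow state to be called FBM and the fast state BM; the printed vectors are
segment-length-weighted class probabilities.  The classifier here trains on
a deliberately small corpus for speed — recall improves with corpus size.
"""

import numpy as np

import sptstates.rnn as rnn
from sptstates import (
    HdpHmmConfig,
    estimate_num_states,
    extract_segments,
    fit,
    state_type_probability,
    summarize_chain,
)
from sptstates import regimes
from sptstates.pipeline import _representative_sample

tracks, truth = regimes.bm_fbm_mixture(n_tracks=250, track_length=100, seed=9)
chain = fit(tracks, HdpHmmConfig(n_iterations=600, burn_in=300, thin=10, seed=10))
k, _, _ = estimate_num_states(chain)
s = summarize_chain(chain)
print(f"inferred {k} states, apparent D = {np.round(s.d_mean, 3)} um^2/s")

labels = chain.state_sequences(_representative_sample(chain, k))
batch = extract_segments(tracks, labels, min_length=20)
print(f"{len(batch)} same-state segments of >= 20 steps")

rng = np.random.default_rng(11)
X, y = rnn.make_classification_corpus(n_per_class=2000, n_steps=20, rng=rng)
spec = rnn.ClassifierSpec(input_steps=20, task="classify", max_epochs=15, seed=11,
                          batch_size=128)
model = rnn.train_classifier(spec, X, y)
print(f"classifier held-out accuracy: {model.holdout_metric:.2f} (chance 0.25)")

probs = rnn.classify_segments(model, batch)
for state, info in state_type_probability(batch, probs, rnn.CLASS_NAMES).items():
    if info["classifiable"]:
        vec = ", ".join(f"{k_}: {v:.2f}" for k_, v in info["probabilities"].items())
        print(f"state {state}: top type = {info['top_type']}  ({vec})")
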