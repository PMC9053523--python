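"""Infer diffusive states from a simulated two-state Brownian mixture.

Simulates 300 tracks of 100 steps switching between a slow (0.135 µm²/s)
and a fast (1.8 µm²/s) state, runs the sticky HDP-HMM blocked Gibbs
sampler, and prints the recovered state count, per-state apparent diffusion
coefficients with posterior spread, weight fractions and the transition
matrix.  The numbers should bracket the simulation inputs: that is the
whole point — the state count is inferred, not supplied.
"""

import numpy as np

from sptstates import HdpHmmConfig, estimate_num_states, fit, summarize_chain
from sptstates import regimes

tracks, truth = regimes.two_state_standard(n_tracks=300, track_length=100, seed=1)
print(f"simulated {len(tracks)} tracks, {tracks.n_steps} displacements, "
      f"true D = {regimes.TWO_STATE_D} um^2/s, weights = {truth.stationary_weights}")

chain = fit(tracks, HdpHmmConfig(n_iterations=800, burn_in=400, thin=10, seed=2))
k, trace, _ = estimate_num_states(chain)
print(f"\nmodal number of occupied states over {len(chain)} retained samples: {k}")

s = summarize_chain(chain)
for i in range(s.n_states):
    print(
        f"state {i + 1}: D_x = {s.d_x[i]:.3f} +- {s.d_x_sd[i]:.3f}, "
        f"D_y = {s.d_y[i]:.3f} +- {s.d_y_sd[i]:.3f} um^2/s, "
        f"weight = {s.weights[i]:.3f} +- {s.weights_sd[i]:.3f}"
    )
print("posterior mean transition matrix:")
print(np.round(s.transition_matrix, 3))
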