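"""Generate the three anomalous-diffusion families and check their scaling.

Each family obeys MSD ∝ t^alpha.  The script simulates ensembles of FBM
(alpha = 0.5 via Hurst exponent 0.25), CTRW (alpha = 0.5 via waiting-time
exponent sigma = 1.5) and Lévy-walk (superdiffusive) paths and prints the
log-log ensemble-MSD slope, which should land near the target exponent
inside each generator's scaling window.
"""

import numpy as np

from sptstates import ensemble_msd_exponent, simulate_ctrw, simulate_fbm, simulate_lw

rng = np.random.default_rng(0)

fbm = simulate_fbm(hurst=0.25, scale=1.0, n_steps=100, tau=1.0, rng=rng, n_paths=4000)
print(f"FBM  H=0.25 : MSD slope = {ensemble_msd_exponent(fbm, 1.0):.3f}  (target 0.5)")

ctrw = np.stack(
    [simulate_ctrw(1.5, 1.0, 2000, 1.0, rng, max_wait_frames=1e5) for _ in range(800)]
)
slope = ensemble_msd_exponent(ctrw, 1.0, min_lag=100, max_lag=1600)
print(f"CTRW sigma=1.5: MSD slope = {slope:.3f}  (target 0.5, fractional window)")

lw = np.stack([simulate_lw(1.5, 1.0, 200, 1.0, rng) for _ in range(2000)])
print(f"LW   sigma=1.5: MSD slope = {ensemble_msd_exponent(lw, 1.0):.3f}  (superdiffusive, > 1)")
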