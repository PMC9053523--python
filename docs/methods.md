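# Methods

## The problem

A single-particle-tracking (SPT) experiment yields thousands of short 2D
trajectories of individual molecules. In a living cell a molecule rarely has
one mobility: it binds and unbinds, gets confined, or is transported, so a
trajectory dataset is a mixture of *diffusive states*, each characterised by
an apparent diffusion coefficient, and molecules switch states inside single
tracks. `sptstates` answers four questions jointly, without fixing the number
of states in advance: how many diffusive states are there, how fast and how
anisotropic is each (D_x, D_y), how do molecules transition between them, and
what kind of random walk does each state perform (Brownian, fractional
Brownian, continuous-time random walk, or Lévy walk), with an estimate of the
anomalous exponent α where applicable.

## Model

### Sticky HDP-HMM with Gaussian emissions

The observed data are single-frame displacements Δx_t (µm). Conditional on a
latent state sequence z_t following a Markov chain with transition matrix π,

    z_{t+1} | z_t ~ π(z_t),      Δx_t | z_t ~ Normal(μ_{z_t}, Σ_{z_t}).

The per-axis apparent diffusion coefficient of a state is D_axis =
Σ_{axis,axis} / (2τ), where τ is the frame interval; for an isotropic state
the 2D mean squared displacement per frame is 4Dτ. The emission mean μ is
estimated rather than pinned to zero, so weak drift does not corrupt Σ; D is
reported from Σ only.

The number of states is inferred with a hierarchical Dirichlet process prior
over the transition rows, truncated at L states (weak-limit approximation):

    β   ~ Dir(γ/L, ..., γ/L)
    π_j ~ Dir(aβ_1, ..., aβ_j + κ, ..., aβ_L)

The sticky mass κ on the diagonal suppresses the over-splitting failure mode
in which one physical state is carved into several look-alike states linked
by rapid artificial switching. Each state's (μ, Σ) carries a conjugate
Normal-inverse-Wishart prior NIW(κ₀, ϑ, ν, Δ) — note κ₀ (a pseudo-count) and
the sticky κ are unrelated.

Inference is blocked Gibbs sampling. Per iteration: (1) each track's whole
label sequence is redrawn jointly from its exact conditional by backward
message passing and forward sampling; (2) auxiliary Chinese-restaurant
"table" counts (with the sticky-override correction on the diagonal), β, the
π rows and each state's (μ, Σ) are redrawn from their closed-form
conditionals; empty states redraw from the prior. Tracks are independent
chains: each track's first label is drawn from a shared initial row
π₀ ~ Dir(aβ + initial-state counts), whose table counts feed the β posterior
like any other restaurant. This initial row matters: with many short tracks
(2,000 × 10 steps) it supplies the rich-get-richer pressure that merges
redundant states — without it the fast state reproducibly over-splits.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| γ | 1.0 | top-level DP concentration (number-of-states prior) |
| a | 1.0 | per-row DP concentration |
| κ (sticky) | 0.1 × total steps | self-transition bias |
| L | 10 | weak-limit truncation; insensitive (tested L = 10 vs 20) |
| iterations / burn-in / thin | 2000 / 1000 / 10 | thin chosen by posterior-sample ACF (first lag with \|ACF\| < 0.1) |
| κ₀, ϑ, ν | 1, (0,0), 4 | weak NIW pseudo-data |
| Δ | empirical displacement covariance | data-scaled NIW scale |
| τ | 0.02 s | 50 frames/s camera |

All coordinates are µm; D is µm²/s. Hyperparameters are weakly informative
and overridable; every fit records its resolved κ and seed.

### Posterior summaries

Retained samples whose occupied-state count equals the modal count are
pooled; their states are matched across iterations by minimum-cost
assignment on |log D| and reported as posterior means ± SD of (D_x, D_y) and
of the step-weight fraction, sorted by ascending mean D. Modal-count ties
break toward fewer states. Label accuracy against simulation ground truth is
the normalized Hamming distance (NHD) under an optimal (rectangular
assignment) label matching, so a global relabelling scores 0.

## Simulators

The Brownian simulator draws a label sequence from a given transition
matrix, then per-axis Gaussian displacements with variance 2·D_axis·τ
(anisotropic states use a (D_x, D_y) pair). The motion-blur variant emulates
camera acquisition: the true walk runs on a grid Texp = 10 times finer with
the off-diagonal transition mass divided by Texp (preserving switches per
frame), each reported position is the mean of Texp consecutive fine
positions, and isotropic localization noise (default σ = 0.03 µm, a typical
experimental uncertainty) is added. Coarse ground-truth labels are the
majority fine label per exposure, ties toward the earlier label.

Anomalous generators: FBM is sampled with exact covariance (Davies–Harte
circulant embedding, Hosking recursion fallback), per-axis covariance
D_H(t₁^{2H} + t₂^{2H} − |t₁−t₂|^{2H}), H = α/2. CTRW draws power-law waits
ψ(t) ∝ t^(−σ) (α = σ − 1) with lower cutoff τ and upper cutoff 1000 frames
by default, Gaussian jumps of fixed variance, immobile between jumps. The
Lévy walk moves at constant speed along uniform headings for power-law
flight durations (σ = 3 − α). Mixed-type Markov-switching tracks scale each
state's per-step displacement variance to 2Dτ, defining the *apparent* D of
a non-Brownian state; FBM memory persists within a dwell and resets at
switches. CTRW/LW states inside mixtures are accepted but flagged, since a
Gaussian emission model does not describe them.

A note on measuring α from simulations: the MSD must be an ensemble average
from the origin (a time-averaged MSD of a CTRW is linear in lag regardless
of α — ergodicity breaking), and the power-law regime is bounded below by
pre-asymptotic corrections near the waiting-time floor and above by the
cutoff-induced diffusive crossover. The scaling tests therefore fit log MSD
over lag windows inside that regime.

## Diffusion-type classifier

Same-state track segments (maximal constant-label runs, ≥ 40 steps by
default, ≥ 20 for the short-input network) are normalized to zero mean and
unit *pooled* variance — one scale factor shared by x and y, preserving
anisotropy cues — and fed to a two-layer LSTM (100 then 50 units) with a
dense head: a 4-way softmax over (BM, FBM, CTRW, LW), or a scalar α
regressor. The implementation is pure NumPy (forward, full backpropagation
through time, Adam with global-norm clipping, early stopping on a held-out
split), deterministic under its seed. Segments longer than the network input
are split into non-overlapping windows whose probabilities are averaged;
state-level type probabilities are segment-length-weighted means, and α
estimates are clipped to the type's valid range. Training corpora are
simulated and class-balanced (refused beyond 10% imbalance); classes are
scale-free after normalization, so unit coefficients are used. Default desk
scale is 20,000 tracks per class with α drawn uniformly over each type's
valid range, 40-step windows, ≤ 25–30 epochs.

## Validation regimes and problem sizes

The canonical simulated regimes (`sptstates.regimes`) are: a two-state
Brownian mixture with D = 0.135/1.8 µm²/s; its sparse (2,000 × 10-step) and
motion-blur variants; a two-state BM + subdiffusive-FBM mixture with
apparent D = 0.045/0.90 µm²/s and α = 0.5; and a four-state mixture
(subdiffusive FBM 0.04, BM 0.2, BM 0.8, superdiffusive FBM 3.0 µm²/s,
α = 0.5 and 1.3). Transition matrices are symmetric and
self-transition-dominant (0.95, and 0.91 for four states), giving uniform
stationary weights; these matrices are this package's choice of realistic
dwell structure. The full-scale validation (500 × 100-step tracks, 2,000
iterations; 20,000-track regression corpus) runs in `scripts/acceptance.py`;
the test suite exercises the same regimes at reduced sizes (e.g. 250–300
tracks, 600–800 iterations, 8,000-track corpus) chosen to keep the
statistical checks meaningful at their stated tolerances.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the model targets —
Markov switching, per-state Gaussian or anomalous steps, exposure averaging,
localization noise — but not out-of-focus loss, photobleaching-limited track
lengths, detection/linking errors, confinement by cell geometry, or spatial
heterogeneity. Passing tests therefore demonstrate correct inference under
the model's own generative assumptions (plus the blur/noise mismatch), not
performance on any particular experimental system.

## Known limitations

* **Motion blur with very short tracks.** Exposure averaging makes
  consecutive observed displacements positively correlated (ρ ≈ 0.25 for
  full-frame exposure). No blur correction is applied to the emission
  likelihood, and with abundant 100-step tracks the bias is only a
  downscaled apparent D. With 10-step tracks, however, the correlation
  inflates the across-track dispersion of apparent variances and the
  iid-Gaussian mixture genuinely prefers several fast sub-states: on the
  sparse motion-blur regime the sampler reports ~5 states instead of 2, at
  every sticky setting tried. State counts from heavily blurred, very short
  tracks should not be trusted.
* **Strongly persistent superdiffusion.** Because μ is a free parameter, a
  superdiffusive FBM state with α ≳ 1.5 can split by drift direction (its
  dwells look like distinct drifting states). The four-state regime uses
  α = 1.3, which is recovered robustly.
* **CTRW/LW states.** Their displacements are non-Gaussian, so per-step
  state labels for such states are unreliable; the classifier can still
  recognise the types on segments, and the simulators flag such mixtures.
* **Short segments.** Diffusion-type classification needs ≥ 20–40 steps of
  a single state; datasets of ~10-step tracks support state inference but
  not type classification.
* The scaled training corpora reach useful but not paper-scale accuracy;
  classification near α = 1 is intrinsically ambiguous between BM and FBM.

## Numerical choices

Backward messages are propagated in scaled probability space anchored at the
per-step maximum log density and renormalised every step (equivalent to
log-space message passing, one matmul per step). Dirichlet draws use gamma
variables floored at 1e-300; near-singular NIW scales are symmetrised with
jitter and logged. The state-sequence sampler, table-count sampler and NIW
update are each validated against independent oracles (brute-force
enumeration over all label sequences at T = 3, sequential CRP seating
simulation, sufficient-statistics recomputation). All randomness flows from
seeded `numpy` generators; chains are bit-reproducible under a fixed seed
and single-threaded execution.
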