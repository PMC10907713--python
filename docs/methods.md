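# Methods

`nbgnet` models the translation of multichannel neural field potentials
between spatial scales — depth-electrode local field potentials (LFP, the
"fine" scale) and skull-screw electrocorticography (screw ECoG, the
"coarse" scale) — in both directions, and evaluates the translations with
the error, similarity, phase-synchrony, latent-dynamics and decoding
analyses standard in motor-systems neuroscience.

## The tissue-impedance state-space template

The medium between a depth electrode and a skull screw (cortex, dura,
three-layer skull, electrode interface) is modeled as a lumped RC ladder:

```
u --R_cortex-- (R_dura ‖ C_dura) --R_compact1-- o --R_compact2-- o--> y
                                                |                |
                                        R_trab ‖ C_spongy    C_interface
                                                |                |
                                               ref              ref
```

Kirchhoff analysis gives a third-order linear state-space model
`x' = Ax + Bu`, `y = Cx + Du` whose states are the three capacitor
voltages.  The network is passive, so `A` is Hurwitz for any positive
parameters (property-tested over 1000 random draws).  The default element
values (kΩ-range resistances, 0.1–1 µF capacitances) put the poles at
roughly 30–110 Hz, i.e. time constants of a few milliseconds — the right
ballpark for tissue filtering at field-potential frequencies — and keep
the forward-Euler discretization stable at the default 1 kHz sampling
rate.  They are ballpark choices, not tissue measurements.

A multichannel transfer allocates one independent 3-state block per coarse
channel, driven by a random weighted sum of all fine channels.  The block
itself has no direct feedthrough (`D = 0`: a shunt capacitor at the
measurement node cannot respond within the same instant), so the assembly
adds a small instantaneous volume-conduction term
`feedthrough_gain * mixing` (default 0.1) to `D`; this is physically
motivated (quasi-static volume conduction is instantaneous at these
frequencies) and keeps the algebraic inverse well posed.

The algebraic inverse of `(A, B, C, D)` is
`(A - B D⁻¹ C, B D⁻¹, -D⁻¹ C, D⁻¹)`.  For singular or non-square `D` a
Tikhonov pseudo-inverse with `eps = 1e-8 ‖D‖²` is used; a `D` that is
exactly zero raises an error naming the vanishing singular value, because
no regularization can recover a missing feedthrough.  Applied to the
*discretized* matrices the same algebra is an exact sample-by-sample
inverse, which is how the forward∘inverse identity is tested.

## The recurrent network

The network implements the causal form of the third-order dynamics with
the unknown constitutive relations replaced by MLPs.  Per output block
`b`: three state-update MLPs `f_{b,k}(q_b, u)` and one readout MLP
`g_b(q_b, u)`, each `input → 7 hidden → scalar`, giving

```
q[t+1] = q[t] + dt · f(q[t], u[t]),      y[t] = g(q[t], u[t]).
```

`dt` defaults to 1, i.e. the state update advances one sample per step
(the recurrence steps at the sampling rate).  Expressing the increment in
seconds instead (`dt = 1/fs`) is mathematically equivalent for a suitably
rescaled `f` but scales every state-path gradient by `1/fs` and stalls
training; the per-sample convention keeps the optimization well
conditioned.  With identity activations and an explicit weight embedding
the network *is* an Euler-discretized linear state-space model; the test
suite exploits this to verify the recurrent core against the analytic
state-space simulator to 1e-10, and the hand-derived backpropagation
through time against central finite differences to 1e-6.

The activation is `tanh` (bounded, smooth; an identity mode exists for the
linear oracle tests).  Weights are Glorot-uniform, biases zero.

### Training

Adam with a starting learning rate of 1e-3, cosine-annealed to 1/30 of the
start over the run; mean-squared-error loss; a 9:1 train/validation split;
one training trial per update, with a freshly drawn trial every 20 updates
(the over-fitting guard); the best-validation parameters are returned.
Numerical safeguards beyond that recipe: global-norm gradient clipping at
10 (the unsaturated identity-mode recurrence can otherwise leave the
stable region early in training), a non-finite-loss guard that rolls back
to the best parameters, and optional truncated-BPTT windows — each update
backpropagates through a random contiguous window (tests use 300–400
samples of the 1600-sample trials) whose first 50 samples are excluded
from the loss while the re-zeroed state settles.  Windowing raises the
update rate about fourfold on the default trials and the burn-in removes
the otherwise-systematic window-start transient from the objective.
Signals are z-scored per channel with training-split statistics before
optimization (the saturating units need O(1) inputs); the normalization is
stored with the parameters so prediction works in volts.

### Effective connectivity

The signed influence of input channel `j` on output channel `i` is the
sensitivity Jacobian `∂y_i,t/∂u_j,t` differentiated analytically through
the readout MLP along the rollout trajectory, averaged over time and
trials (optionally per target direction).  A central-finite-difference
route cross-checks the analytic one to 1e-4.  A latent-to-latent variant
(`∂q_{t+1}/∂q_t` per block) is also provided.

## Baselines

**Four-shell sphere head model.**  A radial current dipole of moment `p`
at radius `r_z` inside a four-layer sphere (brain, CSF, skull, scalp;
radii 27.88/28.24/30.00/31.76 mm, conductivities 0.33/1.65/0.00825/0.33
S/m).  The potential is a Legendre series; the per-harmonic coefficients
are *not* transcribed from any closed form but obtained by solving the
7×7 linear system expressing continuity of `Φ` and `σ ∂Φ/∂r` at the three
interfaces plus `∂Φ/∂r = 0` at the scalp, which makes the implementation
robust to shell changes and directly verifiable against the boundary
conditions.  With equal conductivities it reproduces the single-sphere
closed form (insulating boundary) to 1e-6 — the independent oracle.  The
series truncates at `n_terms` (default 200) or when a term's relative
contribution falls below 1e-10.  The lead field maps a radial-dipole grid
(default four shells at 0.4–0.85 of the brain radius × 900 golden-angle
directions = 3600 dipoles) to electrode potentials; the inverse mapping is
the exact-constraint minimum-norm solution `X = Fᵀ(FFᵀ)⁻¹Y` (the printed
objective's λ is a Lagrange multiplier, not a ridge weight); cross-scale
mapping is the two-step composition through the shared dipole grid.
Synthetic electrode geometry: fine electrodes at 0.9 of the brain radius
(above the dipole grid, as required by the exterior series expansion),
coarse electrodes at the skull radius.

**GRU network.**  Two GRU layers (64, 32 units), two tanh dense layers
(32/16 forward, 32/128 inverse), linear output; L2 weight decay 1e-4 and
per-sequence dropout 0.2 (the published tuning of these two is not
reproduced; fixed values are used).  It trains through the identical
driver as the bond-graph network.  Forward and backward passes of both
networks are hand-written numba kernels validated against finite
differences.

## Metrics

RMSE and the computational-formula Pearson correlation per trial and
channel.  Phase metrics operate on the analytic signal of the beta-band
(12.5–30 Hz) component: a zero-phase 4th-order Butterworth (applied
forward-backward so the phase carries no filter delay), then the Hilbert
transform.  PLV is the modulus of the time-averaged unit phasor of the
phase difference, and its argument is the phase of phase-locking.
IPS(t) = 1 − sin(|Δφ|/2) with phases in degrees and the difference
wrapped to [0°, 180°]; the PSI counts samples with IPS strictly above
1 − sin(22.5°) (0.62 to two decimals — the threshold is stored as the
exact constant, treating the printed 0.62 as its rounding).  The first and
last 5% of samples are flagged as Hilbert edge transients and excluded
from PLV/PSI.  The (PSI, PLV) plane splits at 0.5/0.5 into poor / medium /
perfect synchrony zones.

## Latent dynamics

Per trial, the beta-filtered movement window (onset to onset + 600 ms) is
reduced by PCA to the three leading neural modes; trial-wise loadings are
sign-aligned against the session-mean loading before averaging (PCA signs
are arbitrary).  Two latent trajectory sets are aligned by CCA computed
explicitly as QR decompositions of the centered, transposed trajectories
followed by an SVD of `Q_Aᵀ Q_B`; the canonical correlations (descending
by construction) equal the per-mode Pearson correlations of the aligned
trajectories, which is asserted to 1e-8.  "Instantaneous" correlation is a
sliding-window Pearson correlation (101 samples ≈ two beta cycles), with
0.4 as the display threshold for a strong correlation.

## Decoding

Per channel, 34 features over the movement window: RMS, mean frequency
(power-weighted periodogram frequency restricted to 10–40 Hz), waveform
length, and the periodogram power at each integer frequency 10–40 Hz.
Feature *types* are ranked by Fisher score averaged across channels
(reading the channel-averaged ranking as selecting types; a per-column
mode is available behind a flag), and the top 14 types (28 when two
signal sets are combined, doubling the candidate pool) feed an LDA with
Ledoit-Wolf covariance shrinkage, evaluated by stratified fourfold
cross-validation over the seven input conditions (measured / reconstructed
/ combined signal sets).  Chance level is the shuffled-label accuracy,
~1/8 for the balanced eight-target task.

## The synthetic generator

Sessions emulate a center-out joystick task: eight equiprobable targets,
per-trial movement onset, 160 trials of 1.6 s at 1 kHz, 16 fine and 8
coarse channels (the reduced-channel regime; the sampling rate and trial
length are field-standard stand-ins, as the source data's values are not
public).  Fine channels mix three shared band-limited beta sources whose
amplitude rises from a 0.4 resting level to a cosine-tuned gain
(`1 + 0.5·cos(θ_target − θ_pref)`, random per-channel preferred
directions) during the 600 ms movement window, with 50 ms raised-cosine
edges; on top ride 1/f-power background noise (0.3 of the carrier scale,
independent per channel) and white measurement noise (2e-6 V, ~5–10% of
signal RMS — a measurement-noise-floor regime).  Coarse channels are the
fine channels passed through the tissue-impedance transfer, a normalized
tanh saturation (`(s/γ)·tanh(γ·y/s)` with `s` the session RMS and γ = 1 —
mild but genuine distortion; γ = 0 is exactly linear), and independent
white noise.  The same configuration (including seed) is bit-reproducible.

What the generator does *not* emulate: spatially structured (shared) 1/f
background, non-stationarities across trials, kinematics or eye-movement
signals, and realistic electrode geometry.  One consequence is measured
and worth stating: because each fine channel carries its own independent
1/f background, reconstructing 16 fine channels from 8 coarse channels is
information-limited — a causal 150-lag linear oracle regression reaches a
held-out Pearson correlation of only ≈ 0.79 on the default conditions
(≈ 0.83 even acausally).  Inverse-direction recovery scores should be read
against that ceiling, not against 1: the inverse network approaching ~0.8
is near the best any causal method could do here, which is the synthetic
analogue of the expectation that the inverse mapping performs worse than
the forward one.

## Problem sizes and budgets

The test suite runs every pipeline at desk scale by choice: reduced
channel counts (3–16), 12–160 trials, truncated-BPTT windows, reduced
dipole grids (hundreds of dipoles, 40–150 Legendre terms) and training
budgets of 10²–10⁴ updates.  The method-ordering comparison gives the two
networks equal wall-clock budgets (a GRU update costs roughly an order of
magnitude more than a bond-graph update at these sizes).  All randomness
flows from explicit seeds; training histories are bit-reproducible on the
same hardware/library versions.

## Known limitations

* The inverse direction is representationally capped: 3 latent states per
  output block cannot express long deconvolution filters, and the
  channel-count compression bounds what any method can recover (see
  above).
* The sphere-head two-step mapping is evaluated on sessions whose true
  generator is the tissue-impedance circuit, not a dipole model, so its
  error mostly reflects model mismatch — which is exactly its role as the
  "unrealistic assumptions" baseline.
* Training determinism holds for a fixed BLAS/numba build; bit-identical
  histories across different builds are not guaranteed.
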