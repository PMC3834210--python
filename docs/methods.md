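# Methods

## The model

`anechoid` decomposes a matrix of kinematic trajectories
`X ∈ R^{M×T}` (one channel per row: a joint-angle trace of one trial, or a
marker coordinate) into `N` shared temporal source waveforms that reach
each channel with an individual amplitude and an individual time delay:

    x_i(t) = Σ_j  a_ij · s_j(t − τ_ij) + ε_i(t),      i = 1..M, j = 1..N.

This is the *anechoic* mixing model of acoustics — one direct path per
source and sensor, no reverberation — applied to movement data.  It
generalizes the instantaneous mixing models behind PCA/ICA/NMF by the
per-channel delays `τ_ij`, which is exactly what trial-to-trial and
limb-to-limb phase shifts in locomotion and reaching call for: the left
hip traces the same waveform as the right hip half a gait cycle later, and
a modest number of time-shiftable primitives reconstructs trajectories
that an instantaneous model needs many components to approximate.

Because joint-angle trajectories are smooth and band-limited, every signal
is represented by a truncated Fourier series on the trial window
(harmonics `k = 0..F`, convention `c_k = (1/T) Σ_t x(t) e^{−2πikt/T}`).
Under this representation a delay is a per-harmonic phase rotation
`c_k ↦ c_k e^{−2πik τ/T}`, so delays are continuous parameters and the
model is differentiable in all of `(a, τ, s)`.  The flip side, stated
loudly: **delays are circular over the trial window.**  A source delayed
past the end of the window wraps around.  The synthetic generator applies
delays the same way, so the estimator and the generative model agree; for
real recordings the window should contain whole movement cycles.

## The estimator

Fitting minimizes the Frobenius residual between the data's harmonic
coefficients and the model's, using Parseval weights (1, 2, 2, …) so the
coefficient-domain objective equals the time-domain least squares.
Per-channel temporal means are removed before fitting and restored at
reconstruction.  One restart proceeds as:

1. **Magnitude demixing.**  Delays drop out of coefficient magnitudes, so
   under source independence `|C| ≈ A_abs |S|` with both factors
   non-negative.  This is solved by seeded non-negative matrix
   factorization and initialises the amplitudes and source magnitudes.
2. **Phase update.**  At fixed magnitudes, weights and delays, the source
   phases are updated per harmonic (the objective separates across
   harmonics) by an unconstrained least-squares solve projected back onto
   the magnitudes, with a keep-best guard so the objective never
   increases.
3. **Weight/delay update.**  Given the sources, channels decouple.  Per
   channel and source, the delay maximizing the correlation with the
   residual is found on the integer lag grid (one matrix product per
   source), refined on a 0.1-sample grid, then polished by Newton steps —
   the correlation's derivatives are analytic in the Fourier
   representation, so delays reach far-sub-sample precision.  Weights then
   come from a joint least-squares solve per channel (optionally
   non-negative via NNLS).
4. **Source refresh.**  Per harmonic, the full complex source coefficients
   are re-solved by least squares given weights and delays.  This step
   goes beyond a phases-only iteration: with source magnitudes frozen at
   the NMF solution the model cannot reach machine precision even on
   noiseless, exactly realizable data, whereas the full refresh makes the
   scheme a proper alternating least squares that does.

Steps 2–4 repeat until the relative residual improvement falls below
`tol` (default 1e-5; 1e-6 and beyond only lengthens the noise-dominated
tail without changing the recovered parameters measurably) or
`max_outer_iter` (200) is reached.

### Escaping delay mislocks

Plain coordinate updates have a characteristic failure mode that we
diagnosed on noiseless data where the ground truth has exactly zero
residual: a weakly weighted source on a channel dominated by another
source locks onto *leakage* of the dominant source, or onto a secondary
lobe of its own autocorrelation (a rhythmic source with two similar peaks
has a near-equal autocorrelation lobe half a period away).  These are
genuine local minima of the per-channel delay landscape and of the joint
source/delay landscape.  Three deterministic counter-measures are built
in:

* a **greedy deflation scan** (matching pursuit): per channel, repeatedly
  pick the source with the largest correlation gain against the current
  residual, fix its delay, subtract, continue — this decontaminates the
  weak sources' correlation functions;
* a **lobe-combination scan**: the top two well-separated correlation
  lobes of the most ambiguous sources are evaluated jointly (exact
  residual with jointly optimal weights) and the best combination wins;
* a **pair-grid scan**: for the two highest-energy sources the full
  integer (lag₁, lag₂) grid is evaluated outright — the two-source weight
  solution is closed-form — on the first iteration and periodically once
  progress slows.

All scans keep the incoming solution wherever it is better, so they never
degrade a channel.

### Restarts

The loss surface is multimodal, so the fit runs `n_restarts = 25`
independent initialisations: alternately NMF-based starts (delays uniform
on `[−T/4, T/4]`, phases uniform on `[−π, π)`, an independently seeded
NMF per restart — with a single shared NMF the deterministic scans funnel
every restart into the same attractor and the restarts buy nothing) and
data-driven starts that seed the sources with randomly chosen channels,
every channel being a delayed, scaled source blend.

Two further measures shape the restart phase:

* **Graduated optimization.**  The head start of every restart runs on
  *jittered* coefficients — seeded complex Gaussian noise at 5 % of the
  signal RMS — and only then continues on the clean data.  Spurious sharp
  minima of the delay landscape wash out under perturbation while the
  true basin survives; empirically, fits that stall on exactly noiseless
  data converge cleanly once the search phase is perturbed (measured
  noise in real recordings has the same benign effect, which is what
  suggested the scheme).
* **Successive halving.**  Every restart runs a fixed 12-iteration head
  start; the three lowest-residual states (clean objective) are then
  iterated to convergence, and the lowest final residual wins, ties
  broken by restart index.

Everything is reproducible bit-for-bit from the master seed.

### Canonical form

The model is identifiable only up to source permutation, sign, scale, and
a per-source delay offset.  Reported models fix all four: sources have
unit L2 norm over the trial window and non-negative weight sum; each
source's |weight|-weighted mean delay is zero (a centre-and-wrap
fixed-point iteration, since wrapping into `[−T/2, T/2)` can move the
mean); sources are ordered by explained variance.

## Model selection

**VAF** (variance accounted for) compares a reconstruction against the
row-means baseline: `VAF = 100·(1 − ‖X − X_rec‖²_F / ‖X − X̄‖²_F)`.

**Scree test.**  The VAF-vs-N curve is scanned with trailing-segment
ordinary least-squares regressions, dropping the leftmost point each
round; the smallest starting `N` whose segment has mean squared residual
below 0.001 *on the 0–1 VAF scale* is selected.  A segment must also
*saturate*: its slope must stay below 0.01 (less than one VAF point per
added component).  Without the slope condition a steeply but perfectly
linearly rising curve — no elbow anywhere — would pass the residual check
trivially; with it, the procedure returns "no solution" for such curves
and for the PCA baseline's gradual rise, which is the behaviour the
comparison needs.  Both thresholds are configurable.

**Cross-validation** splits by trial (all channels of a trial stay
together; stratified by condition label when present), fits sources on the
training split, freezes them, re-estimates only per-channel weights and
delays on the held-out trials, and reports the test VAF.  Test trials
demonstrably never influence the trained sources.

**Source alignment** matches two source sets up to permutation, circular
shift and sign.  The default shift is the integer lag maximizing the
absolute correlation (with sign-preserving tie-breaking, needed for
near-antisymmetric waveforms); `method="peak"` aligns maximum peaks
instead, which coincides with the correlation criterion for clean
unimodal waveforms.  Pairing is exhaustive over permutations for up to
four sources, greedy above.

## PCA baseline

Channels are z-scored and the correlation structure diagonalized (via SVD
of the standardized matrix; channel magnitudes differ by an order of
magnitude between upper- and lower-body joints, which is why correlation
rather than covariance).  VAF is computed on de-standardized
reconstructions so both methods are scored on the original data scale.
Component signs are canonicalized by making each component's
largest-magnitude channel weight positive.

## Gait events and reach timing

Foot events are sign changes of a marker's vertical velocity: upward
crossings of a toe marker's velocity are toe lift-offs, downward crossings
of a heel marker's velocity are heel strikes (the direction mapping is
configurable).  Velocity comes from position by central differences, with
an optional zero-phase Butterworth low-pass (default 10 Hz) before the
crossing search; crossing times are interpolated between bracketing
samples, and a 0.2 s refractory period suppresses noise-induced double
crossings.  A gait cycle is the interval between successive same-foot toe
lifts; stance is strike to next same-foot lift as a percentage of the
enclosing cycle.  The reach is timed from the hand-to-origin distance: its
global maximum (parabolically refined, required to be an interior local
maximum) is the contact time, the interval between the bracketing distance
peaks is the reach duration, and the signed intervals to the next four
foot events are the coupling measures.

## Preprocessing

`resample_and_smooth` resamples every channel to 350 points with a cubic
spline over the unchanged time window.  The smoothing penalty is chosen
per channel by generalized cross-validation, with one guard: channels that
pass a noise-free whiteness test (lag-1 autocorrelation of second
differences above +0.5 indicates curvature, not noise) are interpolated
exactly, because a penalized natural spline biases noiseless smooth data
at the boundaries.  Loaders reject NaN unless linear interpolation of
short gaps (≤ 5 samples by default) is enabled.

## The synthetic study

The generator emulates the statistical structure of a combined
walk-and-reach experiment; it makes no claim to biomechanical realism
(no inverse kinematics, no forces).  The default `gait-reach` template:

* **2 sources**: a bell-shaped discrete source (Gaussian bump, width 0.16
  of the cycle ≈ 2σ, centred at 0.45) for the pointing sub-task, and a
  periodic rhythmic source with two peaks per cycle for locomotion.
* **Peak ratio 0.45**: the second rhythmic peak is 45 % of the first,
  matching the strongly unequal double peak of knee flexion (large
  swing-phase peak, much smaller stance-phase peak).  This parameter
  controls identifiability: as the ratio approaches 1 the source's
  autocorrelation side lobe approaches its main lobe and half-period
  delay flips become nearly degenerate — a genuine limitation of anechoic
  demixing with near-symmetric rhythmic sources, not merely of this
  implementation.
* **6 channel groups** (right/left shoulder, hip, knee) × 40 trials =
  240 channels of 350 samples at 120 Hz.  The discrete source loads
  mainly on the right shoulder (weight 1.0 vs ≤ 0.3 elsewhere); the
  rhythmic weights increase toward the lower body (0.15 → 0.9), with
  left-side groups in anti-phase via half-period mean delays.
* **Per-trial Gaussian delays** around the group means (SD 2 % of the
  window), the feature that defeats instantaneous mixing models.
* **Noise**: white Gaussian, SD 5 % of the noiseless mixture's SD.

Dimensionless unit-scale amplitudes throughout; the model estimates scale
per channel, so units are immaterial to every test.  What passing tests on
this generator do *not* show: robustness to non-Gaussian or correlated
sensor noise, soft-tissue artefacts, non-stationary waveform shape within
a session, or delays that are not circularly consistent with the window.

The marker-level fixture (`make_gait_marker_fixture`) provides sinusoidal
toe/heel height channels with analytically known lift/strike times (feet
alternating at a configurable cadence, 60 % stance by default) and a
hand-distance channel with one dominant reach bump — enough structure to
validate the event detector's timing error and the coupling arithmetic,
not a gait simulation.

## Problem sizes and numerical choices

The acceptance-level checks run the pipeline at the study's nominal
conditions (40 trials, 25 restarts, N = 1..5); unit tests use 4–10 trial
versions of the same template, which fit in seconds.  Degenerate inputs
are canonicalized rather than propagated: an all-zero channel gets weight
0 and delay 0; an all-zero magnitude matrix factorizes to zeros; ties
across restarts break by restart index.  Delay precision is limited by
the Newton polish (well below 0.1 samples on clean data); source
correlation comparisons between independent fits are limited to ~0.999 by
integer-lag alignment of narrow waveforms, not by the fits themselves.

## Known limitations

* Exactly one delay per channel–source pair; no convolutive mixing.
* Circular delays (see above).
* Near-symmetric rhythmic sources weaken delay identifiability.
* The scree saturation slope (0.01) is a convention; curves that rise
  steadily by ~1 VAF point per component sit on the boundary.
* Restart budgeting assumes the basin of attraction is decided within the
  head-start iterations; pathological instances could demote the eventual
  winner (raising `n_restarts` or `tol` tightness is the remedy).
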