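# Methods

## Problem setting

A powered prosthetic knee/ankle is driven by an impedance controller: at
every control step the low-level loop applies the torque

    tau_i = -K_i (theta_i - theta_i^eq) - b_i * thetadot_i,      i in {knee, ankle}

where `K` (Nm/deg), `b` (Nm·s/deg) and the equilibrium angle `theta^eq`
(deg) come from a mid-level controller.  Training such a mid-level
controller end-to-end requires long, varied time series of gait data with
matching impedance parameters — data that are expensive to record from
users.  This package implements a generative shortcut: a conditional GAN
learns the map from a coarse, hand-designable sketch of one gait cycle to a
continuous multichannel gait pattern; generated patterns are expanded into
5-ms time series with synthetic impedance profiles; and two small networks
are trained on those series to predict the impedance parameters.

## Data representation

Four channels in fixed order: vertical load (kg), thigh, knee, ankle angles
(deg).  A *gait pattern* holds one cycle over gait-cycle percent, sampled
every 0.5% — either 201 rows (closed grid, 0–100%) for extracted/benchmark
patterns or 200 rows (0–99.5%) for generated ones.  The 200-row form exists
because the generator halves the sequence length three times
(200 → 100 → 50 → 25), so the length must be divisible by 8.  An 11-node
*sketch* specifies a pattern every 10% of the cycle.

All channels share one affine normalization, `v_n = 0.1 v / g + 0.5`, with
gain 36 for angles and, for the load, either the subject's body weight
(benchmark-style data) or a fixed 48 kg (bypass-style data, which preserves
between-subject variability).  Worked values: knee 108° → 0.8, thigh
−72° → 0.3, load 96 kg at gain 48 → 0.7.  The map keeps plausible data in
(0, 1), matching the generator's sigmoid output range.

## Pattern extraction

Raw trials are segmented by a smoothed z-score peak detector (defaults
lag 25 samples, threshold 3, influence 0.1) run on the vertical-load
channel, whose loading-response peak is the most robust once-per-stride
landmark; both the channel and the detector parameters are configurable
since different sensors favour different landmarks.  Runs of flagged
samples collapse to the run maximum, cycles span consecutive peaks, each
cycle is linearly resampled to the 201-row grid, and the element-wise
median across cycles (mean-of-central-pair for even counts) gives the
trial's pattern.  No normalization or offset removal happens at this stage.

## Synthetic benchmark corpus

External motion-capture corpora are replaced by a parametric generator.
Each ambulation mode (level-ground walking, stairs up/down, and a combined
sit-to-stand/stand-to-sit cycle) is a set of fixed per-channel knot tables
interpolated with shape-preserving (PCHIP) cubics; the knots are design
fixtures shaped to qualitative gait features — double-hump load with
near-zero swing load, mono-phasic thigh, biphasic knee, small ankle
excursion — and carry no clinical meaning.  Subjects contribute weight
(sampled uniformly on 55–95 kg), per-channel amplitude scales
(uniform 0.85–1.15, applied about the channel's curve minimum so the load
stays non-negative), phase jitter (std 1% of the cycle, applied as a
monotone PCHIP time warp with pinned endpoints so periodicity survives),
and additive white noise (0.5 kg / 0.5 deg, a plausible sensor-noise
scale).  Trials concatenate per-cycle realizations sampled on [0, 100)% at
5 ms; they start mid-stance by default, since recordings rarely begin
exactly at heel strike (this also keeps the first landmark clear of the
detector warm-up).

What the generator does *not* emulate: inter-joint coupling beyond the
shared phase, ground-interaction effects, asymmetry, fatigue, or any
subject-specific kinematic detail.  Passing tests therefore demonstrate
pipeline correctness and trainability, not clinical fidelity.

## Conditional GAN

Pix2Pix-style translation without a latent noise input.  Generator:
three stride-2, kernel-2 LeakyReLU convolutions (16/32/64 filters), three
transposed convolutions (32/16/4), then a width-200 dense layer with
sigmoid applied along the phase axis with weights shared across channels.
Discriminator: condition and candidate concatenated on the channel axis,
three stride-2 convolutions (16/32/64), an 80-unit LSTM whose
cell-candidate/output activation is LeakyReLU, and a scalar logit head.
Objective: standard conditional adversarial terms plus λ·MAE reconstruction
with λ = 1000; reported generator loss equals adversarial + λ·MAE exactly.
Defaults: Adam, learning rate 0.01, batch 64, 500 epochs.  The 0.01 rate is
kept as the default but is exposed, with 1e-3 as the documented fallback
for corpora on which it diverges.  LeakyReLU slope is 0.2 (the Pix2Pix
convention).  Because no framework autodiff is involved, every layer's
backward pass is verified against finite differences in the test suite.

Generated output is smoothed per channel with a cubic smoothing spline in
the p-parameter convention (p = 0.1 by default; p = 1 interpolates, p → 0
tends to the least-squares line), implemented through the equivalent
roughness weight lam = (1 − p)/p of `scipy.interpolate.make_smoothing_spline`.
Smoothing runs in normalized units, before any denormalization.

## Time-series construction

Sketch variation follows `U' = U + 0.4 σ(U) r` with σ the population
standard deviation over the channel's 11 nodes and `r` uniform on [−1, 1],
drawn independently per node and channel (a constant channel is invariant).
Each varied pattern gets a duration drawn from its mode preset (uniform
1–1.25 s for walking, 5–6.25 s for sit/stand; 60 variations × 10 datasets
at full scale), is linearly resampled to `round(duration / 5 ms)` samples,
and is stitched to its neighbours with one or two linearly interpolated
bridging samples per junction (chosen uniformly at random).  Normalized
impedance profiles — fixed knot tables per joint in [0, 1], stance-high /
swing-low stiffness with damping bumps at the phase transitions — are
expanded to the same durations and stitched with the same junction
treatment, keeping gait and impedance channels sample-aligned.  Physical
ranges for denormalizing impedance: knee 1.5–5 Nm/deg and 0.05–0.5
Nm·s/deg; ankle 3–8 Nm/deg and 0.05–0.15 Nm·s/deg.

## Controller networks

Windows of 50 samples (250 ms) slide over the series; a series of N
samples yields N − 50 − 20 + 1 windows.  The equilibrium network
(input → Gaussian noise σ 0.02 → conv 32/kernel 8/sigmoid → LSTM 20 →
dense 30/10/2, all sigmoid) reads thigh + load histories and predicts the
knee and ankle angles 20 samples (100 ms) past the window end.  The
stiffness/damping network (same trunk, dense head width 4) reads all four
gait channels and predicts the four normalized impedance values at the
window's final sample (the target alignment is configurable; window-end is
the default).  Both train independently for 15 epochs, batch 256, MSE
loss — Adam 1e-3 for the equilibrium net, RMSProp 1e-3 for the
stiffness/damping net.  The Gaussian noise layer is active only during
training, so inference is deterministic.

Equilibrium outputs are sigmoid units mapped linearly onto the mechanical
clamp ranges ([0, 120]° knee, [−8, 8]° ankle), so the limits hold
structurally; `predict_command` additionally hard-clips, so the bounds hold
for arbitrary raw values too.  Training targets are clamped into the same
ranges before unit-mapping — an equilibrium the actuator can never be
commanded to reach is not a meaningful target and sits outside the sigmoid
head's reachable set.  The equilibrium MSE is computed in degrees (each
output weighted by its clamp-range width via the chain rule through the
range map): an unweighted unit-space MSE lets the ankle, whose range is
16° against the knee's 120°, dominate the shared-trunk gradient.

A training-dynamics note: the all-sigmoid stack starts in a regime where
the final hidden features, although already linearly sufficient for the
equilibrium map, carry very small input-driven variance, so the readout
weights must grow large before predictions become input-dependent.  With
Adam's bounded per-step updates this takes a few thousand optimizer steps;
at the full corpus recipe (10 datasets × 60 variations, ≈135k windows,
≈560 steps per epoch) the 15-epoch budget provides them comfortably,
whereas strongly thinned corpora can leave the network predicting the
per-output mean.  LSTM kernels are initialized by the usual framework
convention (Glorot input kernel, per-gate orthogonal recurrent kernel,
unit forget-gate bias).  Because the two networks train independently,
the stiffness/damping network — whose phase-indexed target map is far
easier — may be given a thinned window set to keep its training cheap.

## Evaluation metrics

R² (about the reference mean), RMSE (channel units), a 1-D SSIM with
uniform 11-sample windows, dynamic range 1 on normalized patterns,
C1 = (0.01)², C2 = (0.03)², computed per channel and averaged (the
dissimilarity map is 1 − SSIM per window position), boundary discontinuity
in three modes (201-row last-vs-first; 200-row last-vs-first; and the
interpolated variant, which is exactly half the raw gap by midpoint
algebra), and RMS jerk `J = sqrt(0.5 Σ θ'''(p)²)` with the third derivative
taken by the central five-point stencil (−½, 1, 0, −1, ½)/step³ with
respect to gait-cycle percent (a time step can be supplied instead);
boundary samples where the stencil does not fit are excluded.  The ½ factor
is retained as printed in the defining expression even though RMS
conventions usually use 1/N.

## Reduced problem sizes

The shipped defaults match the full-scale recipe (500 GAN epochs,
60 variations × 10 datasets).  The test suite runs the generator at
reduced scale — a 100-pair corpus and 50 epochs suffice for closure (mean
per-channel R² ≥ 0.9 against the generating template) — while the
controller-recovery check keeps the full corpus recipe, which its training
dynamics genuinely need (see above), on a noiseless (variation-free)
level-ground-walking corpus with random durations.  The sit/stand and
ankle channels are the known weak points: the synthetic sit/stand cycle
has no swing phase, and the synthetic ankle excursion (±15°) exceeds the
±8° ankle clamp, so ankle equilibrium targets saturate at the clamp — the
knee, the clinically dominant joint here, is the recovery criterion.

## Known limitations

* The synthetic templates are qualitative; no claim of biomechanical
  validity.
* The discriminator head and the placement of the generator's final dense
  layer are underdetermined by the architecture strings; the choices above
  (single logit on the final LSTM state; phase-axis dense shared across
  channels) are this package's own.
* Real-time scheduling (5/12/25 ms threads) is not reproduced; `simulate`
  replays windows offline at full speed.
* Training determinism holds for this numpy implementation exactly
  (single-threaded, seeded); it is not expected to match any GPU framework
  bit-for-bit.
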