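# Methods

This note documents the models, algorithms, defaults and design choices in
`sladl`, in the order data flows through the pipeline.

## Problem setting

Manual wheelchair users load the shoulder through a small set of everyday
activities (propulsion, dribbling, weight-relief lifts, transfers, material
handling, arm cranking, desk work, quiet sitting).  Estimating cumulative
shoulder load in daily life requires knowing *which* of these activities is
performed, *when*, and for *how long*.  The package implements a
classification pipeline that labels every 10 Hz timestep of a multi-site
wearable recording with one of the eight activity classes, and evaluates
how well such a classifier generalizes to people it never saw during
training (leave-one-subject-out, LOSO).

## Synthetic cohort generator

No public recordings of the laboratory protocol exist, so the pipeline is
exercised end to end on synthetic cohorts that reproduce the sensor setup:
five sites (wheelchair frame WC, wheel WCW, thorax Thor, upper arm UA,
forearm FA), each with 3-axis acceleration (m/s², 100 Hz) and 3-axis
angular velocity (deg/s, 100 Hz); the upper-arm unit additionally carries
two bipolar surface-EMG channels (biceps long head, medial deltoid,
mV-scale, 1000 Hz).

Per activity class the generator composes each site's channels from

1. **gravity** along a class- and site-specific posture direction (a pitch
   rotation of the vertical; e.g. the forearm is near-horizontal during
   desk work and near-vertical at rest),
2. a **movement component**: a class-specific modulation waveform (pure
   cycle, smooth-edged on/off bouts, or low-pass-filtered "fidgeting"
   noise) scaled by per-site accel/gyro amplitudes and projected on fixed
   per-site axis directions,
3. the **wheel rotation profile** on the wheel gyroscope's rotation axis:
   continuous rotation with a push-cadence ripple for treadmill propulsion
   (160 deg/s steady state, i.e. ~0.85 m/s on a typical 0.3 m radius
   wheel), short bouts that start from and return to standstill for
   dribbling (with occasional backward pushes), and identically zero for
   the six classes without wheel motion,
4. additive Gaussian noise (defaults: accel 0.25 m/s², gyro 2 deg/s).

EMG is generated as a band-limited (20–450 Hz) stochastic carrier with unit
rectified mean, amplitude-modulated by the class's activation envelope plus
a small baseline, and scaled by the participant's reference level — so the
downstream envelope chain sees realistically raw input, and the envelope of
a simulated static-posture hold recovers the participant's reference level
(the basis of reference normalization).

Movement axis directions are fixed **per site, not per class**: the
dominant motion direction at a body site is anatomy-driven.  Classes must
therefore be separated by waveform, amplitude, posture and the wheel
profile.  Two class pairs are deliberately confusable from a single arm
sensor: dribbling shares the arm-level push cycle with propulsion
(resolved by the wheel's bout vs continuous profile), and weight-relief
lifts share the arm-level burst pattern with transfers (resolved by the
trunk excursion on the thorax sensor).  This is what gives the
sensor-subset ablation its expected structure — the full five-sensor setup
outperforms a single arm-worn sensor.

Inter-participant variability: per-modality multiplicative amplitude scales
(log-normal, σ = 0.15), a cycle-frequency scale (uniform ±10%), a random
phase offset, a posture-pitch offset (SD 5°) and log-normal EMG reference
levels.  An overall `NoiseConfig.scale` knob multiplies the noise SDs and
controls task difficulty; all signature amplitudes and the noise defaults
were calibrated once so that the full pipeline reaches the performance
regime the task is known to admit, and are not tuned per experiment.

Schedules default to one block per class, order randomized per participant,
durations uniform in 8–12 s and quantized to 0.1 s (so that 100 Hz IMU and
1000 Hz EMG block lengths stay integer and aligned).  These short sessions
(~80 s/participant) keep full LOSO experiments tractable on one CPU while
leaving dozens of class transitions per cohort; real sessions are longer,
which if anything makes per-sample classification easier (more interior
samples per block).  Everything derives from one integer seed via
`numpy.random.SeedSequence` spawning; regeneration is bit-identical.

**What the generator does not emulate:** kinematic-chain arm motion,
orientation drift or sensor bias, activity sub-structure (e.g. distinct
reach/grasp phases), fluent transitions between activities, or a
"remainder" class of unmodeled activities.  Passing tests on this cohort
therefore demonstrate that the pipeline's machinery is correct and that the
protocol behaves as specified — not that the trained networks would reach
the same numbers on real recordings.

## Preprocessing

* IMU 100 Hz → 10 Hz by non-overlapping block means of 10 samples
  (`out[k] = mean(x[10k:10k+10])`); a moving average followed by
  factor-10 decimation is equivalent at these settings for band-limited
  content.
* EMG envelope: zero-phase (forward–backward) 4th-order Butterworth
  high-pass at 20 Hz → mean subtraction (offset correction; belt-and-braces
  after the high-pass) → rectification → zero-phase 4th-order Butterworth
  low-pass at 2 Hz → decimation by 100 (sample picking; the envelope is
  band-limited at 2 Hz, far below the 5 Hz post-decimation Nyquist).
  Zero-phase filtering doubles the effective attenuation of the stated
  design order.  Negative samples from filter ringing are clamped to 0.
  The forward–backward passes use an edge pad of 6 filter time constants
  (6·fs/cutoff samples) — scipy's default pad is far shorter than a 2 Hz
  transient at 1 kHz, which would otherwise break the zero-phase
  time-reversal symmetry near the signal edges.
* EMG normalization by the static-posture reference level is implemented
  but **off by default** (`normalize=False` in `assemble_features`); the
  classifier input is the raw rectified-smoothed envelope.
* Labels: annotation intervals are half-open `[start, end)`; 10 Hz sample
  k (time k/10 s) takes the class of its containing interval, so a sample
  on a boundary belongs to the starting interval.
* Feature matrices keep native mixed units (m/s², deg/s, envelope scale);
  no normalization, centering or scaling is applied.
* Channel order: sites WC, WCW, Thor, UA, FA, each acc_x..z then gyr_x..z,
  then the two EMG envelopes.  The four sensor combinations are C1 (all
  five IMUs + 2 EMG, 32 channels), C2 (all IMUs, 30), C3 (upper-arm IMU, 6)
  and C4 (forearm IMU, 6).

## Sequence classifier

Per-timestep classifier over eight classes:

    input (T × D, unnormalized) → GRU(100) → biLSTM(200 per direction)
    → dense(8) → softmax,  trained with mean categorical cross-entropy

"200 units" is read as 200 hidden units per direction (400-dim concatenated
output), matching common toolbox semantics; both widths are configurable.
The network is implemented directly in numpy — forward, backpropagation
through time, and Adam — because no deep-learning framework is part of the
dependency set.  Conventions: GRU gates (r, z, n) with
`h_t = (1−z)·h_{t−1} + z·n` and candidate `n = tanh(xW + (r·h_{t−1})U + b)`;
LSTM gates (i, f, g, o) with forget bias 1; Glorot-uniform input kernels,
orthogonal recurrent kernels, all drawn from a generator seeded by the
model seed.  Gradients are verified against central finite differences in
the test suite (norm-relative error < 1e−6 in float64).

Variable-length sequences are zero-padded into one batch; a length mask
confines the loss, and the biLSTM's backward direction reverses each
sequence's valid samples individually so padding can influence neither
outputs nor gradients (asserted by a dedicated test).  Training uses
float32; gradient checks use float64.

Optimizer: Adam, learning rate 1e−3, β = (0.9, 0.999), global-norm gradient
clipping at 1.0, no dropout or weight decay — widely used defaults, all
exposed in `TrainingConfig`.

## LOSO protocol

* One fold per participant: train on all others, validate on the held-out
  one.  A leakage assertion (by participant id) is built into the fold
  result type.
* An **iteration** is one full pass over the training data.  All training
  sequences form a single padded batch, so an iteration is one optimizer
  step, followed by one per-sample accuracy evaluation on the validation
  participant.
* **Early stopping**: the monitor is inert through the first 15 iterations
  (the grace period); afterwards, training stops once the running-best
  validation accuracy has failed to improve for 2 consecutive iterations.
  A constant trace thus stops at iteration 17.  Improvement means a strict
  new maximum.  A hard cap (`max_iters`, default 200) guarantees
  termination.
* The parameters kept from a run are the snapshot at the best-validation
  iteration (earliest on ties), matching the anti-overfitting intent of the
  monitor.
* **Repeats**: each fold is trained `repeats` times (default 5) with seeds
  `base_seed + 1000·fold + repeat`; the repeat with the highest validation
  accuracy is kept (ties → lowest repeat index).  Repeat seeds drive both
  the weight initialization and nothing else (the data are fixed within a
  fold), and are recorded in the run manifest.
* The whole procedure runs once per sensor combination.

## Evaluation

Per fold, per-sample predictions on the validation participant are tallied
into an 8×8 confusion chart (rows true, columns predicted, class order
fixed).  Per class, one-vs-rest counts give

    accuracy = (TP+TN)/total      sensitivity = TP/(TP+FN)
    precision = TP/(TP+FP)        specificity = TN/(TN+FP)

Specificity uses the standard TN/(TN+FP) form; the TN/(TN+FN) variant is
additionally reported as a `specificity_tn_fn` diagnostic column (the two
nearly coincide on TN-dominated charts).  Ratios with zero denominators are
NaN and excluded from summaries.  Summary tables report mean and sample SD
(ddof = 1) in percent over all (participant, class) cells; an alternative
mode first averages within participants.  Boxplot statistics use
linear-interpolation quartiles and 1.5×IQR whisker fences.  Row- and
column-normalized charts (in %) have per-class sensitivity and precision on
their diagonals — asserted as an identity in the tests.

## Problem sizes used in the shipped experiments

The headline synthetic experiment (acceptance script and end-to-end test)
uses a 10-participant default cohort, combination 1, 2 repeats per fold and
at most 60 iterations — 20 training runs that typically early-stop between
iterations 17 and 40.  The ablation-ordering check uses 3-participant
cohorts with 5–7 s blocks over three seeds, one repeat, 18 iterations —
small enough to run routinely while still showing the full-vs-single-sensor
gap.  These sizes are the package's chosen trade-off between statistical
clarity and the cost of training 4×–20× recurrent networks per experiment.

## Known limitations

* The synthetic signatures are parametric templates; claims about real
  recordings require real data.
* Full-batch training (one step per iteration) follows from feeding each
  participant's session as one whole sequence; with many or long sessions,
  mini-batching would change the iteration semantics.
* The numpy implementation is single-threaded-friendly but not
  GPU-capable; at the shipped problem sizes a full four-combination
  ablation on a 10-participant cohort is an hours-scale computation at
  default repeats, which is why the shipped experiments scale it down.
* No "none of the above" class: every sample is forced into one of the
  eight activities.
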