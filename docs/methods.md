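# Methods

This note documents the models, conventions and numerical choices
behind `repform`, in the order the pipeline runs them, together with
what the synthetic-data generator does and does not emulate.

## Raw streams

A recording is nine uniformly sampled channels: accelerometer in g,
gyroscope in °/s, magnetometer in Ga, at 51.2 Hz by default. These
units and full-scale ranges (±2 g, ±500 °/s, ±1.9 Ga) are enforced at
the I/O boundary; orientation math converts gyroscope readings to rad/s
internally. Timestamps must be strictly increasing and uniform to
within 1 µs — synthetic data is exactly uniform, and this tolerance
leaves room for logger jitter in real files. Streams are stored as
plain CSV (`t, acc_x..mag_z`) written with 12 significant digits, so a
write/read round trip is lossless to well beyond 9 digits.

## Signal conditioning

The six inertial channels are low-pass filtered with an 8th-order
Butterworth at 20 Hz, designed as second-order sections and applied
forward-backward (`sosfiltfilt`). Zero-phase filtering was chosen
because the analysis is offline and boundary detection benefits from
zero phase lag; the forward-backward pass squares the magnitude
response, which the filter tests check against the analytic
1/(1+(f/f_c)^2n) curve. The magnetometer is passed through unfiltered:
its error budget is dominated by field disturbance, not wideband noise.
The two magnitude signals are computed from the *filtered* triads, for
consistency with the filtered channels that feed the classifier.

## Orientation

Orientation is estimated with the Madgwick gradient-descent MARG
filter: the quaternion state (sensor→earth) is propagated by gyro
integration and corrected along the normalized gradient of the joint
gravity/magnetic-field objective, scaled by the gain β (rad/s).

* **β = 0.1 rad/s** by default — a standard compromise between
  convergence speed and noise rejection for slow, deliberate limb
  movement; configurable everywhere.
* **Initialization** is algebraic from the first accelerometer and
  magnetometer sample (tilt from gravity, heading from the
  tilt-compensated field), so there is no long convergence transient;
  the filter converges from an arbitrary initial state too, just more
  slowly (seconds at β = 0.1).
* **Degenerate samples**: a zero-norm accelerometer or magnetometer
  sample propagates by gyro integration alone. A numerically zero
  objective gradient (exact agreement between state and measurement,
  which zero-noise synthetic data does produce) skips the correction
  instead of normalizing a round-off vector into a full-size step.
* **Euler convention** is aerospace Z-Y-X: pitch = sagittal inclination
  in [−π/2, π/2], roll = frontal, yaw = transverse, all radians. Within
  1 µrad of gimbal lock, roll is set to 0, yaw absorbs the remaining
  rotation, and a warning is logged.

## Segmentation

Repetitions are delimited on the gyroscope channel with the largest
peak-to-peak range (ties break toward gyro_x < gyro_y < gyro_z; an
explicit channel can be forced). Polarity is canonicalized — if the
largest-magnitude extremum is negative the signal is negated — so
exercises whose dominant lobe is negative segment identically. Local
maxima must clear three thresholds:

* prominence ≥ 0.3 of the signal range (relative),
* separation ≥ 1.0 s (repetitions of these exercises take ≥ 2 s),
* height ≥ 10 °/s (absolute). The relative prominence criterion alone
  cannot reject a recording that contains only sensor noise, because
  noise sets its own range; 10 °/s sits an order of magnitude above the
  ~1 °/s gyro noise floor and well below the ≥ 60 °/s movement peaks.

Epoch boundaries are the zero-crossings bracketing each peak (last
sample ≤ 0 before the rising flank; first sample ≤ 0 after the falling
flank), clamped to the stream edges when a repetition starts or ends
mid-motion, with no sub-sample interpolation so that all 18 channels
slice on identical whole-sample indices. Overlapping epochs (possible
when a trailing crossing is missing) are resolved by truncating the
earlier epoch at the later epoch's start.

## Feature bank

Seventeen descriptors per channel, 306 per repetition. Conventions
that the literal-definition test oracles pin down:

* variance/SD use the population denominator N, matching the
  energy-style descriptors;
* skewness is m₃/m₂^1.5 and kurtosis is Fisher excess m₄/m₂² − 3, both
  defined as 0 for a constant epoch instead of NaN;
* energy is the **sum** of squares (RMS² · N);
* percentiles interpolate linearly between order statistics;
* the crossing level for the level-crossing rate is the epoch mean,
  making the descriptor invariant to sensor offset; the rate is strict
  sign changes of the demeaned signal divided by N − 1;
* the fractal dimension is the Higuchi estimator with k_max = 10 (≈1
  for smooth curves, ≈2 for white noise); a constant epoch returns 1;
* the wavelet descriptors decompose with Daubechies-5, symmetric
  extension, to level 7, and report the population variance of the
  level-7 approximation coefficients and of all detail coefficients
  pooled across levels. Pooling keeps the descriptor count at 17
  (15 + 2); per-level variances would give 21. Epochs too short for 7
  levels (a 1.4 s epoch at 51.2 Hz supports 3 db5 levels) use the
  deepest feasible level — recorded in the vector's metadata — rather
  than manufacturing coefficients from padding.

## Classifier

One forest per exercise per client. Training refuses unbalanced labels
by default; `balance_training_set` removes uniformly random
observations from each overrepresented class until all classes match
the minority count (seeded, deterministic). The forest is the canonical
recipe — 400 bootstrap trees, Gini splits, √p = 17 candidate features
per split, unlimited depth — with the tree count the only deliberately
fixed hyperparameter. Vote fractions come from averaging tree votes
(leaves are pure at unlimited depth); an exact 50/50 tie breaks toward
the "Acceptable" default class, matching the labeling default. The
auto-label workflow surfaces the vote fraction but imposes no
confidence threshold: every proposal is accepted or rejected by the
professional, and rejected proposals leave the repetition unlabeled in
a review queue.

Out-of-bag accuracy is reported as the internal error estimate;
held-out evaluation uses separate sessions never seen at training time.

## Evaluation

"Acceptable" is the positive class: TP = both acceptable, FN = truth
acceptable but predicted aberrant, TN = both aberrant, FP = truth
aberrant but predicted acceptable. Accuracy, sensitivity and
specificity are percentages; a metric with an empty denominator is
reported as undefined (`None`), never as zero. Group reports compute
metrics per participant and summarize mean and population SD across
participants within each group, plus a pooled row.

## Synthetic data

The generator emulates a left-thigh IMU during cyclical lower-limb
exercise. Per repetition, thigh pitch rises from 0 to amplitude A
(default 1.2 rad) as a raised cosine over the descent and returns over
the ascent; an optional roll component R·sin(2πt/T) models
frontal-plane motion. Repetitions are separated by rest gaps (0.5 s)
and their periods jittered (CV 0.05, truncated at ±3 SD). The stream
is rendered exactly: gravity and a fixed earth field (0.4 Ga
horizontal, −0.3 Ga vertical) rotated into the sensor frame, gyro as
finite-difference body rates of the quaternion path, plus i.i.d.
Gaussian noise per channel (0.02 g, 1 °/s, 0.01 Ga defaults). One root
seed with counter-derived per-repetition substreams makes any
repetition reproducible in isolation.

**Descent fraction.** The descent occupies 0.45 of the period rather
than exactly half. The pitch-rate signal has a positive (descent) and
a negative (ascent) lobe; with perfectly symmetric lobes the
segmentation's polarity canonicalization would flip on per-seed
sampling accidents. A slightly faster descent makes the positive lobe
strictly dominant, so the segmented epoch is always the descent phase
— and ground truth records exactly that: per repetition, the
zero-velocity samples bracketing the dominant lobe and its
maximum-rate sample. At zero noise, segmentation recovers these
triples within 3 samples (filter edge effects and finite-difference
offsets account for 1–2).

**Technique deviations**, scaled by a magnitude m ∈ [0, 1]:

| deviation | effect | default study condition |
|---|---|---|
| `amplitude_deficit` | A ← A(1 − m): shallow movement | — |
| `frontal_wobble` | R ← R + 0.4·m rad: valgus/varus-style roll | m = 0.8 |
| `tempo_asymmetry` | descent fraction ← 0.45(1 − 0.5m): rushed descent | — |

At m = 0 the aberrant class is distributionally identical to the
acceptable one, so held-out accuracy must sit at chance — the
end-to-end tests assert both that and ≥ 90 % accuracy at m = 0.8, with
accuracy non-decreasing in m.

**What it does not emulate:** biomechanically validated joint
kinematics, soft-tissue artifact, magnetic disturbance, sensor bias or
drift, linear acceleration of the sensor (the accelerometer sees
gravity only, so ‖acc‖ ≡ 1 g at zero noise — a deliberate invariant
the orientation tests rely on), or between-subject variability.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and internally consistent, not that the reported real-world
accuracy generalizes; the published human-subject results are used only
as printed arithmetic inputs (confusion counts, balancing counts),
which the evaluation module reproduces exactly.

## Problem sizes

The default study conditions are 20 acceptable + 20 aberrant training
repetitions per exercise (the volume an exercise professional collects
in one session) with 10 + 10 held-out repetitions from separate
simulated sessions. The repeated-seed segmentation check runs 100
sessions of 5 repetitions at default noise; oracle-equivalence checks
use 100 random epochs per descriptor.
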