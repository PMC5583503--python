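# repform

Personalized exercise-technique classification from a single body-worn
inertial measurement unit (IMU).

## The problem

Physiotherapists and strength-and-conditioning coaches need to know
whether a client performs a rehabilitation or training exercise (squats,
deadlifts, lunges, single-leg squats, ...) with acceptable technique —
especially when the client exercises unsupervised. A thigh-worn IMU
streaming triaxial accelerometer (±2 g), gyroscope (±500 °/s) and
magnetometer (±1.9 Ga) data at 51.2 Hz captures the limb's motion;
a classifier trained on a client's **own** labeled repetitions can then
flag each new repetition as *Acceptable* or *Aberrant* (e.g. knee
valgus, asymmetry, rushed tempo). Training on the individual sidesteps
the large between-subject variability that plagues population-level
technique classifiers and works for any cyclical, repetition-based
exercise.

`repform` implements that whole pipeline as a library plus CLI:

1. **Signal processing** — accelerometer and gyroscope channels are
   zero-phase low-pass filtered (Butterworth, order n = 8, f_c = 20 Hz);
   sensor orientation is estimated with the Madgwick gradient-descent
   MARG filter and converted to pitch/roll/yaw inclinations (sagittal,
   frontal, transverse planes, radians); accelerometer and gyroscope
   vector magnitudes ‖(x, y, z)‖₂ are derived. Together with the 9 raw
   channels this yields 18 signals per recording.
2. **Segmentation** — repetitions are cut at the zero-crossings
   bracketing each peak of the largest-amplitude gyroscope channel.
3. **Features** — 17 descriptors per signal × 18 signals = **306
   features** per repetition: mean, RMS, SD, kurtosis, median, skewness,
   range, variance, max, min, energy, 25th/75th percentile, mean-level
   crossing rate, Higuchi fractal dimension, and the variances of the
   approximation and pooled detail coefficients of a Daubechies-5
   wavelet decomposition to level 7.
4. **Classification** — training data are balanced by random
   undersampling (each class kept at the minority count), then a random
   forest of 400 trees (Gini, √306 ≈ 17 features per split) is trained
   per exercise per client. Predictions report the tree-vote fraction;
   sensitivity/specificity use acceptable-as-positive conventions:

   accuracy = (TP+TN)/(TP+FP+TN+FN), sensitivity = TP/(TP+FN),
   specificity = TN/(TN+FP).

A built-in simulator (`repform.synth`) generates labeled thigh-IMU
sessions — raised-cosine sagittal excursions with tunable technique
deviations (amplitude deficit, frontal wobble, tempo asymmetry) — with
ground-truth repetition boundaries, so the full pipeline is testable
end to end without human data.

## Worked example

```python
from repform import SynthConfig, TechniqueForest, generate_labeled_dataset

db = generate_labeled_dataset(
    SynthConfig(n_reps=20, seed=0),
    SynthConfig(n_reps=20, seed=0, deviation="frontal_wobble", deviation_magnitude=0.8),
    seed=5,
)
results = TechniqueForest.from_database(db, "squat").fit(seed=0)
print(results.summary())
```

```
Technique Forest Results
======================================================
Exercise:             squat
No. observations:     40
Classes:              Acceptable (n=20), Aberrant (n=20)
Trees:                400
Features:             306
Seed:                 0
OOB accuracy:         1.0000
------------------------------------------------------
Top feature importances
  mag_y__p75                            0.0250
  quat_z__p25                           0.0225
  gyro_x__wavelet_detail_var            0.0200
  ...
```

The 40 simulated repetitions (20 per class, frontal-wobble separation
0.8) train a 400-tree forest whose out-of-bag accuracy is 1.0 — the
wobble shows up exactly where it should, in the frontal-plane (roll-
and x/z-gyro-related) features. `results.predict(feature_vector)`
returns `("Acceptable", 0.97)`-style label/vote pairs, and
`results.auto_label(db)` proposes labels for not-yet-labeled
repetitions for the professional to accept or reject.

The same flow is available from the shell, stage by stage
(`repform simulate | preprocess | segment | features | train | predict |
autolabel | evaluate`) or in one shot:

```bash
repform demo --seed 7 --out-dir demo/
```

which prints the final report (held-out confusion counts and
accuracy/sensitivity/specificity percentages) and writes every
intermediate artifact — stream CSVs, the 18-channel signal set, the
session database, the 306-column feature table, the model archive and
predictions — under `demo/`, each stamped with tool version, config
hash and seed.

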