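# swaybalance

Automatic assessment of standing-balance exercises from a single trunk-worn
IMU.  Each 30 s repetition is recorded as two-channel angular velocity
(pitch and roll, 100 Hz) and classified into an ordinal physical-therapist
rating 1 (steady, independent) to 5 (unable to hold position even with
assistance).  Three representations of the same signal feed three
classifiers:

| representation | model |
| --- | --- |
| 11 hand-engineered kinematic descriptors (RMS, sway path length, 95% ellipse area, in both the angle and velocity domains) | random forest |
| standardized multichannel time series | 1-D CNN (depth-wise grouped conv, 8 filters, kernel 3) |
| 60×60 binary pitch-vs-roll trajectory images (angle + velocity channels, rotation-augmented) | 2-D CNN (same block, 3×3 kernels) |

Ground truth is the mode of a multi-rater PT panel; evaluation uses
exact-match accuracy and macro-averaged one-vs-rest AUROC against
majority-classifier and self-assessment baselines, with paired t-tests
across seeded restarts and Krippendorff's alpha for panel agreement.
Because no public dataset exists, `swaybalance.synthetic` generates
datasets with the assumed statistical structure: band-limited Gaussian sway
whose magnitude grows with a latent severity, pitch/roll anisotropy,
occasional step-out transients, a noisy ordinal rater panel and a
downward-biased self-assessment.

The CNNs are implemented in pure NumPy (a single conv block plus two
fully-connected layers needs no framework), which keeps training exactly
reproducible on CPU.

## CLI

```sh
# generate a synthetic dataset (manifest + per-repetition signal CSVs)
swaybalance simulate --out data/ --seed 0

# the 11 kinematic descriptors, one row per repetition
swaybalance featurize --manifest data/manifest.csv --out features.csv

# 60x60 trajectory images as an .npz archive
swaybalance rasterize --manifest data/manifest.csv --out images.npz

# train one model on the participant-wise split (60/20/20)
swaybalance train --repr image --manifest data/manifest.csv --out model/ --seed 0

# evaluate a trained model on the test participants
swaybalance evaluate --model model/ --manifest data/manifest.csv --repr image --out report.json

# full pipeline: simulate -> split -> train all representations -> table
swaybalance reproduce --out run/ --seeds 30 --max-epochs 2000 --seed 0
```

`reproduce --seeds 3 --max-epochs 100` is a desk-scale variant that
completes on one CPU in a few minutes.

## Data formats

* signal CSV: `time_s, pitch_velocity_dps, roll_velocity_dps` (degrees/s);
* manifest CSV: `repetition_id, participant_id, exercise_id, signal_path,
  pt_rating_1..pt_rating_8, self_rating, step_out_count` (blank cells for
  absent raters);
* exercise metadata YAML: surface / stance / vision / head condition per
  exercise.

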