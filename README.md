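# imutrack

Zero-velocity detection and translational dead reckoning for body-worn
IMUs, with learned and warm-started LSTM components implemented in pure
NumPy.

The pipeline covers:

- **Synthetic data** (`imutrack.synthetic`) — alternating dwell/move trials
  with minimum-jerk movement profiles, corrupted to six-channel inertial
  streams (white noise, bias random walk, slow "gravity-leak" sinusoid,
  state-scaled Ornstein–Uhlenbeck gyro).
- **Zero-velocity labeling** (`imutrack.labeling`) — windowed-displacement
  labeling of a position track with a hysteresis multiplier, plus
  accuracy/precision/recall scoring and grid calibration.
- **Fixed-threshold detectors** (`imutrack.threshold_detectors`) — SHOE
  (variance-normalized accel+gyro energy) and ARED (gyro energy), with
  accuracy-maximizing threshold calibration on training trials.
- **Learned detectors** (`imutrack.ml_detectors`) — 11 time-domain features
  x 6 channels into LR/SVM/RF with group-3-fold CV and seeded random
  hyperparameter search; LSTM(30) and six-layer LSTM(80) sequence
  classifiers on raw standardized windows; binary median-filter
  post-processing.
- **Dead reckoning** (`imutrack.integration`) — Euler double integration,
  zero-velocity gating, and per-segment linear drift removal.
- **LSTM regressors** (`imutrack.regressors`) — two-layer displacement
  regressors with three warm-start strategies (analytic "integrative"
  weights that reproduce Euler double integration before training;
  pre-trained single-integration weights, plain and drift-corrected; plain
  random init with 3/6/9-channel inputs), and a stacked network that
  jointly detects zero-velocity and regresses whole-trial displacement
  under a convex BCE/MSE loss.
- **Metrics** (`imutrack.metrics`) — per-axis RMSE/MAE/R², 3D ATE and 3D
  MAE, aggregated mean ± sd across trials.
- **Experiments** (`imutrack.experiments`) — end-to-end detection-accuracy
  and detector × regressor tracking-error matrices with YAML manifests.

All neural components (LSTM forward/backward-through-time, Adam with
weight decay and global-norm gradient clipping, early stopping with
best-weight restore) live in `imutrack.nn` and depend only on NumPy.

## CLI

The `imutrack` entry point exposes the pipeline stages:

```sh
# simulate 3 subjects and write trial/label CSVs + manifest
imutrack simulate --out-dir data --n-subjects 3 --seed 1

# zero-velocity labels from the position columns of a trial CSV
imutrack label data/S00_rsho_00.csv --out labels.csv

# calibrate and run a fixed-threshold detector
imutrack calibrate --method ared --trials data/S00_rsho_00.csv \
    --labels data/S00_rsho_00_labels.csv --out ared.yaml
imutrack detect data/S00_rsho_00.csv --method ared --params ared.yaml \
    --median-kernel 31 --out detected.csv

# gated dead reckoning with drift removal, then evaluate
imutrack track data/S00_rsho_00.csv --labels detected.csv --out est.csv
imutrack evaluate data/S00_rsho_00.csv est.csv

# train/predict displacement regressors and the stacked network
imutrack train-regressor --data-dir data --variant integrative --out model
imutrack predict data/S00_rsho_00.csv --model model \
    --labels data/S00_rsho_00_labels.csv --out pred.csv
imutrack train-stacked --data-dir data --alpha 1.0 --out stacked

# full experiment matrices
imutrack experiment --kind detection --out-dir runs --seed 0
```

### Trial file format

One CSV per (subject, placement, trial) with header
`t,ax,ay,az,gx,gy,gz[,px,py,pz]` (seconds, m/s² gravity-removed linear
acceleration, rad/s angular velocity, metres). Identity is encoded in the
filename as `<subject>_<placement>_<index>.csv`; `imutrack simulate`
writes matching `*_labels.csv` files (`t,label`, 1 = stopped) and a
`manifest.yaml` recording specs and seeds.

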