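# Methods

## Data model

A task recording couples two synchronized IMU streams (arm, wrist), each a
tri-axial accelerometer in g and gyroscope in °/s at 128 Hz, with a
segmentation into one complete-task interval and three subtask phases.
Intervals are 0-based half-open `[start, end)` sample indices, which removes
the off-by-one ambiguity inherent in manually labeled segment boundaries.
Units are kept as recorded (g, °/s): every feature below is either
unit-agnostic or reported in these units, and gravity is deliberately *not*
removed from the accelerometer — the feature bank operates on raw signals,
so the gravity projection itself carries postural information.

## Synthetic cohorts

Real recordings of this kind come from clinical cohorts and are not
shareable, so the simulator is the package's data source. It is built to
reproduce the signal phenomenology the features consume, not shoulder
biomechanics:

- **Trajectory model.** Each task is a single rotational degree of freedom
  (elevation for WH/POH, an internal-rotation path for WUB/WLB/ROP) with a
  task-specific peak excursion (70°–160°) and three phases: lift, sustain,
  return, flanked by 0.5 s of quiet standing. The lift and return are
  superpositions of `n_submovements` time-shifted minimum-jerk strokes
  θ(τ) ∝ 10τ³ − 15τ⁴ + 6τ⁵; one stroke yields the single bell-shaped
  velocity profile of fluent movement, several overlapping strokes the
  fragmented profile of guarded movement. The sustain phase oscillates at
  2 Hz (scrubbing/holding).
- **Sensor model.** The gyroscope is the analytic derivative of the joint
  angle distributed over a fixed task-specific rotation axis. The
  accelerometer is 1 g projected through the instantaneous limb angle plus
  tangential (r·θ̈/g) and centripetal (r·θ̇²/g) components at the sensor
  radius; hence ‖α‖ ≈ 1 g whenever the arm is still. The wrist sensor sits
  further from the joint: its movement-induced amplitudes are the arm's
  scaled by a fixed lever factor of 1.6, which also makes wrist features
  carry a better signal-to-noise ratio — the mechanism behind the
  wrist-beats-arm comparison below. White Gaussian noise is added per
  channel (tremor on the accelerometer, rate noise on the gyroscope).
- **Group profiles.** Healthy: amplitude ×1.0, duration ×1.0, 1 stroke,
  tremor 0.02 g, gyro noise 1 °/s. FS: amplitude ×0.6, duration ×1.5, 3
  strokes, tremor 0.05 g, gyro noise 2 °/s, weaker sustain oscillation.
  Between-subject variability is multiplicative lognormal jitter (relative
  SD 0.1 by default) on the continuous scales, seeded per subject from the
  master seed. The effect directions follow the clinical picture (reduced
  range of motion, slowness, movement fragmentation, guarding); their
  magnitudes are package configuration, not clinical claims — no public
  effect-size estimates exist for these features in this population.

What the simulator does *not* emulate: multi-joint coupling and
compensatory trunk motion, sensor drift and calibration error, age/sex
confounds, heteroscedastic pain-dependent behavior within a session, or
overlap between mild FS and healthy movement. At the default jitter the two
groups are strongly separable, so classifier accuracies near 100% on
synthetic cohorts say only that the pipeline recovers a separation the
generator put in; they are not expected accuracies on clinical data. The
jitter parameter is the intended knob for making the problem harder when
stress-testing classifiers.

## Feature definitions and numerical choices

- **Statistical bank.** SD and variance are population moments (divide by
  n); skewness is the standardized third central moment, kurtosis is excess
  kurtosis (normal → 0), both set to 0 whenever the channel SD is zero up to
  float round-off (≤ 1e-12 relative). Order is statistic-major: for each of
  the eight statistics, the seven acceleration channels then the seven
  angular-velocity channels.
- **NMCP** counts strict sign changes of (signal − segment mean); samples
  exactly on the mean do not count. **NP** counts local maxima with
  topographic prominence ≥ 5% of the segment's range (raw local maxima
  would count sensor noise); a flat segment has zero peaks.
- **SPARC** follows the established spectral-arc-length construction: the
  magnitude spectrum of ‖ω‖, zero-padded by four octaves, normalized by its
  DC value, truncated at the highest frequency ≤ 10 Hz still reaching the
  0.05 amplitude threshold, and its arc length (with frequency normalized by
  the cutoff) negated. The padding level, threshold and cutoff are exposed
  as parameters. At the default padding the value differs from the
  continuum arc length by O(grid spacing); the test suite verifies the
  integrator against an independent chirp-z dense quadrature at converged
  padding, where agreement is within 1e-3.
- **LDLJ** is −ln( T³/v²_peak · ∫ (v″)² dt ) on v = ‖α‖. The duration
  exponent 3 is the dimensionless choice for an acceleration-magnitude
  input, making the metric invariant under both amplitude and duration
  rescaling. The second derivative uses a 4th-order central stencil in the
  interior (2nd-order at the edges) and trapezoidal integration; with a
  2nd-order-only stencil the duration invariance at 128 Hz holds only to
  ~3e-2, with the 4th-order stencil to ~2e-3. Degenerate inputs (zero peak
  or zero jerk) raise a dedicated error rather than returning ±inf.
- **PI** is the summed per-axis product of acceleration range and
  angular-velocity range, pairing (x,x), (y,y), (z,z).
- **Durations** of subtask segments are their sample span over the sampling
  rate; the complete-task duration equals the annotated complete interval's
  span. The per-segment duration is attributed to the wrist in
  placement masks, since task duration is operationally defined by the
  wrist leaving and returning to its initial position.

## Reduction

Standardization is the z-score with population statistics; columns with
zero training variance map to 0. PCA is an SVD of the centered
(standardized) training matrix with a deterministic sign convention (the
largest-magnitude loading of each component is positive); the retained
dimension is the smallest k whose cumulative explained-variance ratio
reaches the threshold (0.95 or 0.99). Both are fit inside each training
fold and applied to the held-out subject; a `fit_scope="global"` option
exists for deliberate comparison with whole-dataset preprocessing, which
leaks test information and is not the default.

## Classifiers

Classical kinds use scikit-learn / XGBoost with widely used defaults
(SVM-RBF C = 1, gamma = "scale"; random forest 100 trees; AdaBoost 50
estimators; gradient boosting 100 trees, depth 3, learning rate 0.3;
Gaussian naive Bayes), all seeded. KNN breaks even-k vote ties toward the
nearest neighbor's label. The MLP (1–3 fully-connected+dropout blocks) and
the 1-D CNN (1–2 blocks of same-padded convolution → batch normalization →
ReLU → max-pooling 2, then dropout → ReLU dense → softmax) run on a minimal
seeded numpy engine with mini-batch Adam (batch 32), cross-entropy loss, at
most 100 epochs, and early stopping once the epoch training loss fails to
improve on its best value by ≥ 0.01 for 10 consecutive epochs. Training
loss is monitored (no validation split is carved from the small folds).
The CNN consumes the canonical feature ordering as a single-channel
sequence. Hyperparameter grids (hidden units {16,32,64}, dropout
{0.1,0.3,0.5}, learning rate {1e-3,5e-4,1e-4}, kernel {3,5,7}, filters
{16,32,64}) are validated at spec construction; when a grid is searched,
selection is by LOSOCV accuracy reported transparently — like the KNN
k-sweep, this is selection on the test protocol and is flagged as such.

## Evaluation

One fold per sampled shoulder (a bilateral patient contributes one subject
per shoulder); all five task instances of the held-out subject form the
test set. Metrics are computed on confusion counts pooled over folds
(micro-averaging) because each fold contributes only five instances and
per-fold ratios are unstable; the literal per-fold average is also
computed and reported. FS is the positive class. Zero-denominator ratios
are reported as 0 and flagged.

## Problem sizes

The default study scale is 26 FS + 20 healthy subjects (230 task
instances, ~948 features each). At this scale the full nine-classifier
comparison over three sensor placements runs in roughly ten minutes on a
single CPU, the 1-D CNN accounting for most of it; the unit-test suite
uses an 8-subject cohort for pipeline contracts and reserves the full
cohort for the end-to-end discrimination checks.
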