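# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `armtrack`. Empirical figures quoted here are the ones
the test suite and `scripts/acceptance.py` themselves compute.

## Frames, units and sign conventions

The device x-axis points along the arm; y and z complete a right-handed
device frame. The world frame is z-up with nadir = (0, 0, −1) and x along
the horizontal projection of magnetic North. Accelerometers are in g with
the *gravity-vector* convention: a stationary device whose x-axis points
at nadir reads aₓ = +1 g, i.e. the static reading is the device-frame
direction of gravity. This is forced by the accelerometer-only elevation
formula θ = cos⁻¹(aₓ/‖a‖): a hanging arm must give θ ≈ 0°, an overhead
arm θ ≈ 180°. Gyroscopes are stored sensor-native in °/s and converted to
rad/s only inside integration; magnetometers are calibrated unit-norm
directions (norm outside [0.5, 1.5] is rejected as uncalibrated).

Whether the x-axis points proximally or distally is not observable from
the rest pose alone; the package fixes "distal positive, aₓ = +1 g when
hanging" and the simulator adopts the same convention, so all internal
quantities are consistent.

## Orientation filter

The attitude estimator is a quaternion complementary filter of the
propagate-then-correct family (Mahony/Madgwick style). Per sample:

1. propagate q by the trapezoidal average of the last two gyro readings
   over dt (exact axis-angle exponential, so constant-rate integration is
   error-free up to axis commutation);
2. form a body-frame error vector e = w_a·(â × v̂) + w_m·(m̂ × n̂), where
   â is the normalised accelerometer reading, v̂ = Rᵀ(0,0,−1) the
   predicted gravity direction, and the magnetometer term compares the
   measured field with a dip-free reference rebuilt from the measured
   field itself (so magnetic distortion can only steer heading, never
   elevation);
3. rotate the estimate by `gain · e` and renormalise.

Parameters (all in `FusionConfig`):

| parameter | default | meaning |
|---|---|---|
| `gain` | 0.1 | dimensionless per-sample correction fraction; at 50 Hz this is a ≈0.2 s time constant. 0 disables correction (pure gyro integration). |
| `accel_gate` | (0.05, 0.2) g | gravity correction has full weight while \|‖a‖−1\| < 0.05 g and fades linearly to zero at 0.2 g |
| `rate_gate_dps` | 250 °/s | gravity correction disabled above this rate |
| `mag_weight` | 0.5 | relative weight of the heading term |
| `init` | triad | initial attitude solved from the first accel+mag sample |

The two gates implement shock tolerance: during a throw the accelerometer
measures many g of linear acceleration and its direction is meaningless,
so the filter coasts on the gyro for those few hundred milliseconds and
re-converges afterwards. The gain is deliberately small enough that even
partially open gates cannot drag the estimate far within an impulse, yet
large enough to absorb a 0.5 °/s gyro bias with a sub-degree steady-state
error. On noise-free simulated throw sessions the filtered elevation
tracks ground truth to ≈1–2° RMS while the accelerometer-only estimate
errs by ≈7–11° RMS (tens of degrees inside the impulse windows).

No online gyro-bias estimation or magnetometer hard/soft-iron calibration
is performed (out of scope).

## Event-count histograms

`hist_and_count` assigns each sample of a scalar series to its nearest
bin center (ties to the lowest index, making results platform-stable) and
keeps two tallies: the classic histogram, and a debounced event count in
which a bin increments only when its previous occupancy lies more than
`event_spread = 1 s × fs` samples in the past. The occupancy marker
refreshes on *every* assignment, so sustained occupancy counts once, and
the marker initialisation guarantees the first visit always counts (a
zero-initialised marker would suppress events in the first second of a
recording, contradicting the intent of counting "separate times").

The implementation counts per bin via gaps between assignment indices;
the test suite proves it equivalent to a literal sample-by-sample history
re-scan on 1000 random series up to 10⁴ samples, including exact-tie and
first-second cases. Default bins are 20°-wide for elevation and
150 °/s-wide for rate; note that a fast sweep (throw release traverses
~500 °/s between consecutive 50 Hz samples) can skip a narrow rate bin
entirely — counting *peaks* reliably needs bins wide enough that the
signal dwells in them, which is why the high-rate demonstrations use
500 °/s bins.

## Stage-1 detector

A raw trigger fires where `elevation > 45°` AND `rate > 400 °/s`, both
strict, evaluated on the filtered elevation and the gyro magnitude. Raw
triggers are debounced against the last *counted* trigger with a 1.0 s
refractory period; all raw triggers inside the refractory window are
absorbed into one event anchored at their rate-magnitude peak. Debouncing
against the last counted trigger (rather than merging trigger runs by
gaps) was chosen because it makes the event count a greedy maximum
packing, which is provably monotone: raising either threshold shrinks the
trigger set and can only reduce the count. Run-merging does not have this
property (thinning a long run can split one cluster into two), and the
monotonicity guarantee is the more valuable contract for threshold
tuning. For well-separated athletic motions the two semantics coincide.

The extraction window is 2.0 s with 40% before the anchor — long enough
to capture wind-up and follow-through of a throw at 50 Hz (100 samples),
with the high-energy release just before the window midpoint. Edge
windows are truncated, zero-padded back to nominal length (attitude and
elevation are edge-replicated instead, since a zero quaternion is not a
rotation) and flagged.

## Features

Each segment yields exactly 81 named values:

* 36 order statistics: min, max, range, median of acceleration, rotation
  rate, and per-axis elevation relative to gravity (angle between each
  device axis and nadir, from the fused attitude), for the three axes;
* 3: the rotation-rate vector at the sample of maximum arm elevation;
* 3: the unit rotation axis at the sample of maximum rate (zero vector
  when the peak rate is below 1 °/s, where the axis is undefined);
* 39: mean FFT magnitudes of the rotation rate per axis in 13 bands.

The spectra are unwindowed ‖rfft‖/n magnitudes; a band mean averages the
bins whose center falls in [lo, hi), so all band features are invariant
to circular time shifts of the segment. The 13 bands per axis are an
11-band exact tiling of (0, 25] Hz — 0–0.5, 0.5–1.5, 1.5–2.5, 2.5–5,
5–7.5, 7.5–10, 10–12.5, 12.5–15, 15–17.5, 17.5–20, 20–25 — plus the two
broad aggregates 5–10 and 10–25 Hz. The aggregates exist because the
reduced classifier needs them as *single* features; a flat partition
cannot simultaneously contain 0–0.5, 0.5–1.5, 2.5–5, 5–10 and 10–25 as
atoms and still have 13 members, so the registry is "exact tiling + two
aggregates" rather than a pure partition. The partition property is
asserted on the 11 fine bands.

The default reduced model uses eight features: the x and z components of
the rotation axis at peak rate, the x-axis range of motion relative to
gravity, and the band means y:5–10, y:10–25, z:0–0.5, z:2.5–5 and
x:0.5–1.5 Hz. These are geometrically sensible: a throw is
internal-rotation-dominant (axis ≈ ±x), a serve is an elevation-plane
swing (axis ⊥ x), and the band energies encode the differing impulse
durations. `forward_select` implements the greedy wrapper (add the
feature that maximises stratified-CV accuracy, stop at k or at a
plateau) for re-deriving subsets on new data.

## Classifier and null-class gate

`train` fits a scikit-learn `BaggingClassifier` of 160 unpruned CART
trees (bootstrap resamples of training-set size, default split criterion)
on a stratified 40% of the segments, holding out 60% for testing —
stratification protects the small Neither class. Class scores are
per-tree vote fractions (not averaged leaf probabilities), so "96 of 160
trees vote Throw" scores exactly 0.60. A segment is accepted as Throw or
Serve only if the winning sport class has a vote fraction ≥ 0.60
(inclusive); otherwise it is Neither and is reported but not counted.
Models pickle to a single artifact and reload with identical predictions.

Null-class training examples are produced the way false detections arise
in deployment: a loosened stage-1 rule (elevation > 30°, rate > 75 °/s,
0.6 s refractory) is run over the control sessions and every detection
further than 1.5 s from any true sport event becomes a Neither example.
The exclusion zone matters: without it, split-off echoes of real serves
were labelled Neither and serve recall collapsed, an instructive label-
noise failure mode.

## Simulator

Each activity is a list of key poses in three angles — elevation θ,
azimuth ψ, axial roll — joined by minimum-jerk interpolants (zero
velocity and acceleration at every key, hence C² trajectories). The
attitude is R = Rz(ψ)·Ry(90°−θ)·Rx(roll); the gyro signal is the analytic
angular velocity of that rotation in the device frame (finite differences
of the emitted attitude reproduce it to ≪1 °/s RMS on exercise-speed
motion); the accelerometer senses device-frame gravity plus the second
derivative of a point 0.13 m along the arm; the magnetometer senses
device-frame North (no inclination/dip — the filter's dip handling is
exercised only by its own reference construction).

Template anchors: throws sweep ~150° of internal rotation in ~0.16 s
(peak magnitudes ≈1200–2400 °/s across subject scales and per-rep
jitter), at ~100° elevation; serves swing the elevation plane through
~95° in ~0.22 s (≈600–1100 °/s) from ~150° elevation; every resistance
exercise stays below ~250 °/s at any elevation (Flexion reaches ~165°
slowly, External Rotation at the Side stays below ~20° elevation), so
the 45°/400 °/s rule separates sports from the null class with margin.
The throw's follow-through is a deceleration phase slow enough to fall
back under the rate threshold, so one throw is one trigger run.

Noise defaults: 1 °/s rms gyro white noise, 0.5 °/s per-axis constant
bias, 0.02 g accelerometer noise, 0.01 magnetometer noise; optional
±2000 °/s per-axis gyro clipping is off by default so multi-axis
composition can reach ~2400 °/s magnitudes. All randomness flows from
the session seed through one `numpy` generator, so sessions are
byte-reproducible.

`default_benchmark_suite` emulates the two-protocol acquisition: 11
subjects, each with a control session (seven exercises then the two
sports, fixed order, 8 repetitions) and a randomized session (shuffled
order, 2–6 exercise reps, 4–12 sport reps), with a persistent per-subject
±15% speed scale.

What the simulator does **not** model — and hence what passing tests do
not show about real data: soft-tissue and strap artefacts, true throwing
biomechanics (kinetic chains, inter-subject style differences beyond a
scalar speed scale), magnetic dip and indoor field distortion,
temperature-dependent bias drift, sampling jitter, and any overlap
between sport and exercise signatures as extreme as real novice athletes
can produce. Recovery scores near 100% on synthetic sessions therefore
validate the pipeline's correctness, not its field accuracy; the
published field experiment of this design reported high-80s to mid-90s
percent accuracies.

## Evaluation conventions

Detections and ground-truth sport events are matched greedily one-to-one
within 0.6 s of the event's peak-rate time. Event-level confusion rows
are true sport events (missed → Neither column); unmatched detections
form the Neither row. Bland-Altman statistics use d = algorithm −
observed per session (undercounting ⇒ negative mean difference), a
t-based 95% CI of the mean with n−1 degrees of freedom, classical
mean ± 1.96·sd limits of agreement, and Pearson r with an explicit
degenerate flag for constant inputs; the CI of the mean and the limits
of agreement are both reported because summaries labelled "95%
confidence interval" in this literature can denote either.

## Problem sizes and determinism

The shipped benchmark trains on 11 control sessions (~230 s each,
~800 harvested segments) and evaluates 20 randomized sessions, which
keeps the full test suite under half a minute and the acceptance script
at a similar scale on one CPU. Hypothesis-based property tests are
derandomised; every stochastic test and script draws from fixed or
CLI-provided seeds.
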