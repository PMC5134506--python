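# armtrack

Single-IMU tracking of overhead arm motion for workload monitoring in
throwing sports. A 9-axis inertial unit (tri-axial accelerometer,
gyroscope, magnetometer at 50 Hz) strapped to the upper arm is enough to
count baseball throws and volleyball serves in free-living data that is
dominated by *other* arm movement — resisted shoulder-rehabilitation
exercises, transitions, rest — provided the pipeline handles the
windowing problem and a large null class. Overuse injuries of the
shoulder and elbow correlate with throwing volume, so an unsupervised
counter of overhead motions is the pedometer-equivalent that coaches and
clinicians lack.

The package is aimed at researchers in wearable-sensor biomechanics and
human activity recognition who need a tested, reusable implementation of
this pipeline plus a ground-truthed simulator to benchmark it against.

## The method

1. **Orientation fusion (AHRS).** A quaternion complementary filter
   propagates the attitude with the gyroscope and corrects drift with the
   accelerometer (gravity) and magnetometer (North). Arm elevation is the
   angle between the along-arm device x-axis and nadir,

   θ = cos⁻¹((DCM · [1,0,0]ᵀ) · [0,0,−1]ᵀ),

   where the DCM maps device vectors to the world frame. The
   accelerometer-only estimate θ = cos⁻¹(aₓ/‖a‖) is also computed; it
   breaks down exactly during throws, when linear acceleration swamps
   gravity, which is why fusion is needed.

2. **Event-count histograms.** Besides a classic histogram of elevation
   or rate (time spent per bin), a debounced counter reports how many
   *separate times* each bin was visited: a new event is counted only
   when the bin was last occupied more than one second earlier.

3. **Two-stage spotting and classification.** Stage 1 flags a candidate
   whenever `elevation > 45°` **and** `angular rate > 400 °/s` (strict),
   debounced at 1 s and anchored at the rate peak; a fixed 2 s window is
   cut around the anchor. Stage 2 summarises the window into 81 named
   features (order statistics, rotation-axis geometry, FFT band means of
   the rotation rate) and scores it with a 160-tree bagged decision-tree
   ensemble trained on a stratified 40% split. The winning sport class
   must carry ≥ 60% of the tree votes, otherwise the event is "Neither".

4. **Agreement statistics.** Confusion matrices, accuracy, and
   Bland-Altman analysis of per-session counts (mean difference of
   algorithm − observed, 95% CI, limits of agreement, Pearson r).

5. **Synthetic sessions.** Since no public recordings exist for this
   protocol, `armtrack.synthetic` generates ground-truthed sessions:
   minimum-jerk orientation trajectories per activity (throws, serves,
   seven resisted exercises, rest), analytic gyroscope signals, gravity +
   lever-arm accelerometer signals, sensor noise and bias, and the two
   acquisition protocols (fixed-order control, randomized validation with
   2–6 / 4–12 repetitions).

## Worked example

```python
from armtrack import synthetic as syn
from armtrack.orientation import estimate_series
from armtrack.spotting import spot
from armtrack.benchmark import recovery_benchmark
from armtrack.classification import run_pipeline

rec, truth = syn.generate_session(syn.sports_script(8, 8, seed=3))
series = estimate_series(rec)
print(len(rec), "samples, peak rate %.0f deg/s" % rec.rate_magnitude.max())
print("stage-1 detections:", len(spot(series.theta, series.rate_mag, rec.fs)))

model, summary = recovery_benchmark(seed=1, n_sessions=20)
result = run_pipeline(rec, model)
print("counts:", result.counts, "| truth:", truth.sport_counts)
```

prints

```
3529 samples, peak rate 2036 deg/s
stage-1 detections: 16
counts: {'Throw': 8, 'Serve': 8} | truth: {'Throw': 8, 'Serve': 8}
```

All 16 overhead motions (8 throws + 8 serves) trigger stage 1 — the
throws peaking around 2000 °/s of internal rotation — and the trained
ensemble assigns every one to the correct sport. `recovery_benchmark`
trains the ensemble on 11 simulated control sessions and scores 20
randomized sessions; `summary.recall`, `summary.mean_count_error` and
`summary.agreement` hold the per-class event recall, signed count error
and Bland-Altman statistics.

The same stages are available from the shell:

```bash
armtrack simulate --preset sports --seed 3 --out session.csv --truth truth.csv
armtrack fuse session.csv --out fused.csv
armtrack detect session.csv --out events.csv
armtrack count session.csv --out report.csv
armtrack train --from-simulation --seed 1 --out model.pkl
armtrack classify session.csv --model model.pkl --out decisions.csv
```

Custom sessions use a YAML script,
`{subject_scale: 1.0, blocks: [{activity: baseball_throw, reps: 5}, ...]}`,
passed as `armtrack simulate --script script.yaml`. Every output carries a
`*.manifest.yaml` with the config hash and seed.

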