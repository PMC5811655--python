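# pocketgait

Gait assessment from a smartphone carried in the front trouser pocket.

Walking while doing something else — talking, calculating, deciding — is a
demanding cognitive-motor task, and the *dual-task cost* to stride timing
is a sensitive window on locomotor and brain health. Measuring it normally
requires an instrumented walkway in a laboratory. A phone in the pocket
carries the same class of inertial sensors, and its stride-time estimates
can be validated against such a walkway. `pocketgait` implements that
pipeline for researchers in digital health and gait analysis:

1. **Earth-frame rotation** — each device-frame accelerometer/gyroscope
   sample is rotated by the phone's attitude quaternion *q*,
   `v_earth = R(q) · v_device`, so the z-axis points vertically regardless
   of how the phone sits in the pocket.
2. **Zero-phase filtering** — a 4th-order low-pass Butterworth (5 Hz
   cutoff) applied forward–backward, so filtered extrema keep their timing.
3. **Gait events** — filtered vertical acceleration shows two peaks per
   stride alternating high/low; the trough nadir after each *high* peak is
   the phone-side heel strike, after each *low* peak the toe-off. Stride
   time = samples between consecutive heel strikes ÷ 100 Hz.
4. **Turn excision** — vertical angular velocity is segmented at zero
   crossings; a segment is a turn when `AUC × duration > 2.00 rad·s`,
   where AUC = |∫ω_z dt| is the angular distance (a 180° turn ≈ π rad).
   Strides overlapping turns are excluded.
5. **Outcomes and statistics** — per-trial mean stride time, dual-task
   cost `100·(T̄_dual − T̄_normal)/T̄_normal`, and the validation battery:
   Passing–Bablok orthogonal regression, Bland–Altman limits of agreement,
   Pearson r², and one-way ICC(1,1)/ICC(1,k) test-retest reliability.

A ground-truth simulator (`pocketgait.simulate`) generates pocket-IMU
trials with known event times, arbitrary fixed phone orientation, sensor
noise and turn pulses of exact angular displacement, so every stage is
testable without hardware.

## Worked example

Simulate a 45-second home walking trial containing two 180° (π rad) turns,
then analyze it:

```bash
$ pocketgait simulate --out demo --seed 42 --turn "18.0,3.1416,2.0" --turn "33.0,3.1416,2.0"
wrote demo/recording.csv (4500 samples, 41 strides, 2 turns)

$ pocketgait analyze demo/recording.csv --setting home --out demo/results
{"condition": "normal", "mean_stride_time_s": 1.0502941176470588,
 "n_peaks_repaired": 0, "n_strides_dropped_implausible": 0,
 "n_strides_excluded_turning": 6, "n_strides_included": 34,
 "n_turns_detected": 2, "sd_stride_time_s": 0.039195337858014746, ...}
```

The trial was generated with mean stride time 1.05 s; the pipeline
recovers 1.0503 s from the 34 strides that stayed clear of the turns, and
excludes the 6 strides overlapping them. The turns table shows both turns
found with angular distance ≈ π:

```bash
$ head -3 demo/results/turns.csv
start_s,end_s,auc_rad,duration_s,score
17.93,20.54,3.176222519523337,2.6108810038791788,8.292739040316745
32.65,35.28,3.1737162371066785,2.632885981920346,8.356032991271162
```

Both scores far exceed the 2.00 rad·s threshold; straight-walk wobble
segments score ~0.02 rad·s and are never flagged. From the library, the
same analysis is three calls:

```python
import pocketgait as pg

rec = pg.read_recording("demo/recording.csv", "wide_csv")
res = pg.analyze_trial(rec, pg.TrialMeta(setting="home"))
print(res.summary.mean_stride_time)   # 1.0502941176470588
```

`pocketgait validate test_strides.csv ref_strides.csv` matches two stride
tables (heel strikes paired within ±0.25 s) and prints the Passing–Bablok
slope/intercept with CIs, the Bland–Altman bias and limits of agreement,
and r²; `pocketgait icc table.csv` computes ICC(1,1) or ICC(1,k) from a
subjects × trials matrix.

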