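# Methods

## Signal model and pipeline

A pocket-worn phone records device-frame acceleration **a**(t), angular
velocity **ω**(t) (both 3-D, nominally 100 Hz) and a per-sample unit
attitude quaternion *q*(t) (scalar-first *w,x,y,z*) describing the active
rotation from the device frame to an earth-fixed frame whose z-axis is
vertical. The pipeline is:

    rotate → filter → peak detection → high/low labelling → trough-nadir
    events → stride times → (home trials) turn detection + stride masking
    → trial summary → dual-task cost / agreement statistics

**Rotation.** `v_earth = R(q)·v_device`, with R(q) the quaternion rotation
matrix. Quaternions are renormalized at load; a zero-norm quaternion is a
hard data error. The convention (active rotation, scalar-first) is locked
by oracle tests against an independent quaternion-to-matrix formula and
the composition identity R(q₁q₂) = R(q₁)R(q₂). Attitude estimation from
raw inertial data is out of scope: quaternions are a required input, and
the simulator generates them.

**Filtering.** 4th-order low-pass Butterworth, 5 Hz cutoff, applied
forward–backward (`filtfilt`) to both vertical channels. Zero phase
matters because event times are read from filtered extrema; any phase lag
would bias stride times. 5 Hz keeps the 1–2 Hz gait fundamental and its
informative harmonics while suppressing sensor noise. Both order and
cutoff are config keys (`filter_order`, `filter_cutoff_hz`). Note the
digital (bilinear-transform) design matches the analytic magnitude
1/(1+(f/f_c)^{2n}) in the passband and at the prewarped cutoff but
attenuates *more* than the analog formula toward Nyquist; tests check the
passband analytically and the stopband against the designed digital
response. Gravity is retained in the vertical acceleration (event logic
uses extrema, so a constant offset is irrelevant); `subtract_mean_accel`
removes it if desired.

**Gait events.** Candidate peaks: local maxima with prominence ≥ 0.3 × SD
of the filtered channel and spacing ≥ 0.2 s (both configurable). The
high/low labelling assigns "high" to the index parity maximizing
mean(high) − mean(low); a trial where neither parity separates is
rejected as ambiguous. A high peak smaller than both neighbouring lows
flags a spurious detection; the smallest-prominence peak in that triple
is dropped and labelling re-run (repair count logged). Each peak's event
is the minimum of the filtered signal between it and the next peak: heel
strike after a high peak, toe-off after a low one; the final peak yields
no event. Stride times are differences of consecutive heel-strike sample
indices divided by the sampling rate; values outside 0.4–2.5 s (healthy
stride times run ≈1.0–1.2 s; the bounds exclude artifacts without
touching plausible dual-task slowing) are dropped and counted. Only
phone-side-leg events are claimed.

**Turns.** The filtered vertical angular velocity is split into maximal
constant-sign runs (exact zeros terminate a run; trial edges act as
crossings). Each segment is integrated trapezoidally between its two
bounding zero crossings, located by linear interpolation between the
boundary sample and its outside neighbour — this makes both the angular
distance (AUC) and the duration refer to the crossing-to-crossing
interval rather than to the sample run alone, which at 100 Hz would
otherwise clip up to two sample intervals from every turn. AUC is the
absolute integral: turn direction depends only on which way the phone
faces in the pocket and is discarded. A segment is a turn when
AUC × duration > 2.00 rad·s (config `turns_threshold_rad_s`). Filtering
the gyroscope channel before segmentation is the default
(`turns_filter_wz`), since unfiltered tremor-band ripple fragments
segments; an unfiltered mode exists. A stride [hs_i, hs_{i+1}] is
excluded iff it overlaps a turn interval expanded by `turns_buffer_s`
(default 0 — only the turning period itself is removed).

**Outcomes.** A trial summary is the mean and SD of included stride
times (≥ 2 required; otherwise the trial is flagged with a typed error).
Dual-task cost = 100·(T̄_dual − T̄_normal)/T̄_normal from a matched pair of
trials; assessment-level aggregation is the unweighted mean of trial
means.

## Agreement statistics

**Passing–Bablok.** All C(n,2) pairwise slopes; ties in x skipped
(counted), slopes of exactly −1 discarded. The slope is the median of the
sorted slopes with its rank shifted by K = #(slopes < −1), which makes
the estimator invariant under exchanging the two methods; the intercept
is median(yᵢ − b·xᵢ). CIs use the classical rank-based normal
approximation, C = z₀.₉₇₅·√(n(n−1)(2n+5)/18), chosen over bootstrap
because it is deterministic and directly testable against a brute-force
enumeration oracle. Exact scale equivariance and the swap identity
b(y~x)·b(x~y)=1 hold in the method-comparison regime (no slopes at or
below −1, odd slope count); tests exercise exactly that regime.

**Bland–Altman.** Differences d = y − x: bias = mean(d), limits of
agreement = bias ± 1.96·SD(d), plus the (mean, difference) table and an
optional matplotlib plot.

**ICC.** One-way random-effects (Shrout–Fleiss case 1) only, matching the
single-rater test-retest design: ICC(1,1) = (MSB−MSW)/(MSB+(k−1)MSW),
ICC(1,k) = (MSB−MSW)/MSB, with 95% CI and p from the F distribution of
MSB/MSW. Negative estimates are reported as computed — truncating at zero
would bias the null-simulation checks. MSW = 0 with MSB > 0 returns
exactly 1 with a degenerate CI; an all-constant table is an error.
Two-way ICC forms are out of scope.

**Stride matching.** To pair two event streams (app vs reference mat),
heel strikes are matched one-to-one by greedy nearest-neighbour within
±0.25 s; a stride pair is kept when consecutive reference heel strikes
map to consecutive test heel strikes.

## Synthetic-data generator

The simulator emulates exactly the features the pipeline consumes, and no
more. Earth-frame vertical acceleration: per stride of duration
Tᵢ ~ truncated-Normal(1.05 s, 0.05 s) (truncated at the plausibility
bounds), a high Gaussian bump (2.0 m/s², σ 0.06 s) at stride onset, a
−1.5 m/s² trough 0.15 s later (the heel strike), a 1.25 m/s² bump at
mid-stride and a trough 0.15 s after it (the toe-off), riding on gravity.
All event centres are snapped to the sample grid, so ground-truth stride
times are exact sample counts. Vertical angular velocity: a sinusoidal
straight-walk wobble (0.1 rad/s, period ≈ one stride) plus, per
configured turn, a half-sine pulse of amplitude θπ/(2T) whose integral is
analytically the turn angle θ. White Gaussian noise is added to the
earth-frame channels; the emitted device-frame recording is their exact
rotation by the inverse of a fixed orientation quaternion (given or
uniformly random), with that quaternion attached to every sample — so
the pipeline's earth-frame rotation must undo it to machine precision.

Default amplitudes (high:low ratio 1.6, trough −1.5 m/s²) were chosen
once to give the alternating-peak morphology with comfortable prominence
margins at realistic noise; 45 s at a 1.05 s mean stride yields ~42
strides, and excising two 2-s turns leaves counts in the 20s–30s,
matching field experience with home trials.

What the generator does **not** emulate: double-support timing, arm
swing, soft-tissue artifact, pathological gait, attitude-estimate drift,
or turns that alter the concurrent stride pattern (the acceleration
waveform continues through a turn; only the masking logic, not stride
biomechanics during turning, is exercised). Passing the simulation suite
therefore demonstrates correctness of the algorithms under the stated
signal model, not clinical validity on new populations — that requires
instrumented-walkway data, which enter this package only as generic
stride-time tables.

`simulate_study` operates at the trial level (subject baseline ~
Normal(1.05, between-SD), dual-task scaling 1 + cost/100, trial jitter ~
Normal(0, within-SD)): it feeds the reliability and dual-task-cost
harnesses, which consume only trial means, without paying for waveform
synthesis of hundreds of trials.

## Numerical and design choices

- Irregularly sampled input (median interval off nominal by >1%) is
  linearly resampled to the nominal grid; quaternions are renormalized
  after interpolation. Gaps > 3 nominal intervals produce a warning.
- Exact-zero angular-velocity samples terminate a segment (deterministic
  tie-break; measure-zero on real data).
- Stride tables round-trip bit-exactly through CSV (floats serialized at
  full repr precision).
- Trial-boundary peaks: the parity labelling is global, so a trial
  starting mid-stride is handled without special-casing the first peak.
- Problem sizes in the test harnesses (100 trials for stride recovery, 50
  for the turn operating point, 200 replicates for reliability, 1000 for
  the ICC null) were fixed in advance as the smallest designs that make
  the sampling error of each check small relative to its margin.

## Known limitations

- Requires per-sample attitude quaternions; recordings without them are
  rejected rather than fused on the fly.
- Contralateral-leg events, swing/stance decomposition, walking speed and
  stride-time-variability metrics are out of scope.
- The Passing–Bablok CI uses the large-sample rank approximation; for
  n < ~10 the bracket indices are clipped to the observed slope range.
- r² is Pearson's, computed alongside the orthogonal fit and labelled as
  such.
- Turn intervals extend to the nearest zero crossings, so detected bounds
  include a fraction of the adjacent straight-walk oscillation (up to
  half a wobble period per side); masking is correspondingly slightly
  conservative.
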