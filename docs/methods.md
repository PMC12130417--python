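# Methods

This note records the signal-processing definitions, the generative model
behind the simulator, its calibration algebra, and the statistical
conventions used by the cohort summaries. Everything here is a package
design decision; where a convention has common alternatives, the choice
and its rationale are stated.

## 1. Vibration metric

Let `g(t) = (gx, gy, gz)` be a triaxial accelerometer sample stream at
sampling rate `fs` (default 1000 Hz).

1. **Magnitude norm.** `m(t) = sqrt(gx² + gy² + gz²)`. Using the
   omnidirectional magnitude makes the metric independent of sensor
   mounting orientation.
2. **Brick-wall bandpass 10–375 Hz, edges inclusive.** The real FFT of
   the whole record is taken, every coefficient whose bin frequency
   `k·fs/n` lies outside `[10, 375]` Hz is set to zero, and the signal is
   inverse-transformed. This is an exact projection: in-band sinusoids
   pass unchanged, out-of-band ones vanish to numerical precision, the
   operation never adds energy (Parseval) and is idempotent. The lower
   edge removes gravity, posture and slow drift; the upper edge removes
   out-of-band noise while keeping the pump fundamental and its first
   harmonics (a centrifugal pump at 2800–3750 rpm has its fundamental at
   47–62.5 Hz).
3. **Windowed RMS.** The filtered magnitude is cut into consecutive,
   non-overlapping 30-s windows; each window yields
   `RMS = sqrt(mean(x²))`. A trailing partial window is dropped. One hour
   of recording therefore yields exactly 120 values.

The default order is *norm first, then filter* (`order="norm_first"`);
filtering each axis before the norm (`order="filter_first"`) is also
provided. The two differ because the norm is nonlinear; norm-first is
the default because the magnitude is the physically meaningful quantity
and the filter then acts on exactly the signal being summarized.

### Per-timepoint extraction

Protocol timepoints are instants (e.g. "15 min after reversal"). The
default extraction rule, `window_ending_at`, takes the value of the last
complete window ending at or before the timepoint and requires that
window to end within one window length of it (anything older is stale
and raises). A `mean_of_k_windows` rule (mean of the last k complete
windows) is available for noisier channels. Window boundaries are
compared against protocol instants with a 1 µs tolerance, because
boundaries reconstructed from a CSV-inferred sampling rate differ from
exact instants in the last few ulps.

## 2. Statistics

- **Cohort cells** are reported as `median (min–max)`; with even n the
  median is the mean of the two central values.
- **Relative change** is `100 · (value − baseline) / baseline`, computed
  per subject and then summarized; the cohort median of relative changes
  is *not* the relative change of the medians, and the per-subject order
  is what the paired test needs.
- **Exact Wilcoxon signed-rank.** Differences of zero are dropped by
  default (`zero_policy="drop"`; Pratt's method is available). Tied
  absolute differences receive mid-ranks; ranks are doubled to integers
  so that the full null distribution of the positive-rank sum can be
  enumerated exactly by dynamic programming over integer counts (no
  floating-point probability accumulation). The two-sided p is
  `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Enumeration is used up to 25
  informative pairs; beyond that a normal approximation with continuity
  correction takes over (at n = 30 the two agree to ~0.01).
- **Floor of the exact test.** With n distinct informative pairs the
  smallest achievable two-sided p is `2 / 2ⁿ`; at n = 7 that is
  0.015625, reported as 0.02 at two decimals. Seven consistent
  same-direction changes in a seven-subject crossover therefore always
  yield p = 0.02, and an unchanged channel yields p = 1.00.
- Significance is flagged at p ≤ 0.05. `scipy.stats.wilcoxon` is used in
  the test suite only as an independent cross-check; the package's own
  implementation is the one under test and supports exact tie handling.

## 3. Simulator

### Protocol

Two phases, mirroring a pump-speed sweep followed by anticoagulation
reversal:

- **Phase 1:** three steady segments at low / medium / high pump speed
  (2800 / 3250 / 3750 rpm; flows 3.5 / 4.0 / 4.5 L/min), default 600 s
  each. Extraction at each segment's end.
- **Phase 2:** return to baseline speed (`pre_reversal`), then a reversal
  event followed by a 3600-s watch with extraction at +900 / +1800 /
  +3600 s (`t15`/`t30`/`t60`). Circuit flow dips slightly after reversal
  (3.5 → 3.3 → 3.2 → 3.3 L/min) as the clot loads the circuit.

All segment boundaries are multiples of the 30-s window, and the pump
speeds are chosen so every window holds an integer number of pump
revolutions — harmonic window RMS is then exactly `A/√2` with no
leakage. Harmonic phase accumulates continuously across speed steps.

Two short protocols exist for fast statistical work: `compact()` (90-s
segments, watch extraction at 90/180/270 s) and `lead_time_study()`
(phase 2 only, no flow dip, configurable pressure lag). These are
test-scale choices of this package, not claims about any experimental
protocol.

### Generative model (per subject)

Vibration is a scalar process along the sensor's mount axis `u` (unit
vector parallel to the gravity offset, default `(2,3,6)/7`):

```
g_a(t) = u_a · (|G| + v(t)),  a ∈ {x, y, z}

v(t) = Σ_k A_k sin(2π k θ(t) + φ_k)          pump harmonics, f0 = rpm/60
     + D sin(2π f_drift t)                    sub-band drift (0.3 Hz)
     + ε(t),  ε ~ N(0, σ(t)²)
σ(t) = σ0 · (Q(t)/Q_ref)^e · (1 + gain(t))
```

The triaxial norm is then exactly `| |G| + v(t) |`, which stays positive
for the default amplitudes, so the injected in-band power — and hence
the expected windowed RMS — is available in closed form rather than
having to be measured through the very pipeline under test. The
baseline RMS scale is set to 0.06 g to stay safely in that linear
regime; the analysis targets are relative changes, which are
scale-invariant.

The flow-dependent broadband noise (`σ ∝ Q^e`) carries the pump-speed
effect. The thrombosis effect is a monotone saturating gain applied to
the broadband noise after the reversal event:
`gain(t) = max_gain · φ(t − onset)` with the logistic-shaped profile
`φ(s) = 2/(1 + e^(−s/τ)) − 1` (0 at onset, → 1). This is a stated
phenomenological effect model, not clot physiology.

The transmembrane pressure channel is `ΔP(t) = a_lin·Q + a_quad·Q² +
c·φ(t − onset − lag) + noise`, i.e. the *same* clot profile delayed by
`lag_s` (default 900 s). The vibration-first detection property is thus
a property of the model, with the lead time recoverable by the analysis.
The flow coefficients interpolate ΔP = 12 / 18 / 26 mmHg at 3.5 / 4.0 /
4.5 L/min. Auxiliary hemodynamic channels (heart rate, MAP, CVP, mPAP,
SpO₂, ACT) are simple baselines plus noise; ACT follows a piecewise-
linear post-reversal fall so its pre/post comparison is a genuine
change, while e.g. SpO₂ stays flat (its paired test reports p = 1).

Between-subject variability is multiplicative log-normal on the
harmonic amplitude, noise level and thrombosis gain (σ_ln = 0.10, 0.10,
0.15). Per-subject seeds are derived deterministically from the master
seed (`(seed + 1000003·(i+1)) mod 2³¹`), so cohorts are reproducible
subject by subject and byte-identical across runs.

### Calibration

The free effect parameters are solved so that the *expected*
cohort-median relative RMS changes equal configurable targets (defaults
+23.1 % at medium speed, +135.0 % at high speed, +6.4 % at the first
post-reversal timepoint):

1. With all harmonics in-band and integer cycles per window, expected
   window RMS² = harmonic power `H` + in-band noise power `N`. The two
   pump-speed targets give
   `((Q_hi/Q_b)^2e − 1)/((Q_med/Q_b)^2e − 1) = (R_hi² − 1)/(R_med² − 1)`,
   solved for the flow-noise exponent `e` by bracketed root finding
   (`e ≈ 8.85` at the defaults — a phenomenological value, not a fluid-
   dynamics claim).
2. `N = (R_med² − 1)·P0 / ((Q_med/Q_b)^2e − 1)` and `H = P0 − N`, where
   `P0` is baseline RMS². Harmonic amplitudes follow a fixed 1 : 0.5 :
   0.25 profile scaled to `H`.
3. The white-noise standard deviation is `σ0 = sqrt(N/β)`, where `β` is
   the exact fraction of white-noise power the brick-wall band retains
   (sum of in-band rfft bin weights, ≈ 0.73 for 10–375 Hz at 1 kHz).
4. The reversal target fixes `max_gain` through the quadratic
   `m2·g² + 2·m1·g + 1 = target`, where `m1, m2` are the mean and mean
   square of the clot profile over the extraction window.

Closed-form per-timepoint expected RMS values (and relative changes) are
stored as ground truth for every simulated subject; tests verify their
statistical *recovery* by the pipeline, never the targets against
themselves.

## 4. Detection lead time

For each subject, both channels are reduced to the same 30-s window
grid (RMS for vibration, window mean for ΔP). Each channel's baseline
is the median of the complete pre-reversal windows; its detection time
is the start of the first post-reversal window exceeding
`baseline · (1 + threshold)`. The lead is `t_ΔP − t_RMS` (> 0 means
vibration first); a channel that never crosses makes the lead
right-censored at the remaining observation span. Matched thresholds
default to half of each channel's expected plateau fractional rise, so
neither channel is privileged. With the default 900-s pressure lag the
recovered median lead is ≈ 870 s — the lag minus one window of
discretization.

## 5. Limitations

- The simulator is a phenomenological effect model; its noise exponent,
  logistic clot profile and mount-axis geometry are chosen for exact
  ground truth and calibratable effect sizes, not as physical claims.
- The brick-wall FFT filter processes whole records (no streaming) and
  assumes regular sampling (1 % jitter tolerance on ingest).
- The exact signed-rank test enumerates up to 25 informative pairs;
  beyond that the continuity-corrected normal approximation is used.
- Absolute RMS levels in g depend on sensor and mounting; all headline
  quantities are relative changes for that reason.
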