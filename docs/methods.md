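# Methods

This note documents the models, assumptions and numerical choices behind
gaitsmooth, in the order the pipeline runs them.

## Signal model and preprocessing

A trial is a set of body-worn sensors (hip, left/right thigh, left/right
shank, left/right foot), each contributing a triaxial accelerometer
(m/s²) and gyroscope (°/s) stream with a common implicit time base. Axes
follow the x = yaw, y = pitch, z = roll convention; for a foot-mounted
sensor the pitch axis is the mediolateral (flexion–extension) axis and
carries the event-bearing content. Units are kept native: SPARC and LDLJ
are dimensionless and the Peaks Metric is a count, so no unit conversion
is forced.

Conditioning has three steps:

- **Resampling to 100 Hz** with an anti-aliased polyphase FIR
  (`scipy.signal.resample_poly`), the conversion ratio approximated as a
  rational number to within 1/1000. Polyphase resampling was chosen over
  linear interpolation because the latter attenuates content near the
  Nyquist frequency. FIR resampling has a short edge transient (a few
  filter lengths); analyses that compare against analytic signals exclude
  a guard band at the edges. Trials already at 100 Hz skip this step.
- **Low-pass filtering**: fourth-order Butterworth, 5 Hz cutoff (walking
  fundamentals are 1–2 Hz), applied forward–backward (`sosfiltfilt`).
  Zero-phase application was chosen because event *timing* is the
  pipeline's first product and group delay would bias it; the price is
  that the effective attenuation is that of an eighth-order filter.
- **Resultants**: the per-sample Euclidean norm across the three axes.

Non-finite samples: runs of at most 2 consecutive interior NaNs are
linearly interpolated on loading; anything longer (or edge NaNs) rejects
the trial. Real IMU streams drop occasional samples; longer gaps are not
recoverable without inventing data.

## Event detection and segmentation

Foot-off (FO) is the maximum of the foot gyroscope pitch channel once per
stride; foot-strike (FS) the maxima of the foot accelerometer pitch
channel. "Maximum" needs guards on real signals, so peak picking uses:

- a minimum peak separation of half the dominant period, estimated from
  the first autocorrelation peak beyond 0.3 s (fallback period 1.0 s);
- a prominence threshold of 0.3 × (95th percentile − median) of the
  channel;
- a height threshold at the channel median plus the same prominence
  value. Prominence alone admits noise-born peaks flanked by deep noise
  dips in the standstill parts of a recording; requiring the peak to also
  stand above the channel's upper spread removes them without touching
  genuine event peaks, which are several times larger.

All three guards are configurable (`events:` block). Events are detected
only on foot sensors; other locations inherit the foot-derived
segmentation.

**Stride convention.** A stride is anchored FO → next FO, with swing
[FO, FS) first and stance [FS, next FO) second. The conventional FS → FS
anchoring is available via `events.stride_anchor: foot_strike`; the
FO-anchored reading is the default because it makes swing and stance tile
the stride exactly with the FS as the single interior event. Swing and
stance durations always sum to the stride duration by construction.

**Trial rules.** The first and last stride of each side are discarded
(acceleration, deceleration and turning contaminate them), and a trial is
valid only if at least four strides per side remain. Invalidity is a
status with a reason string, not an exception, and every exclusion is
logged — exclusion accounting is a first-class output.

**Temporal parameters.** Cycle time is the mean stride duration; step
time the mean interval between successive foot-strikes of alternating
sides (undefined with a single instrumented side); cadence is 60/step
time; swing percentage the mean per-stride swing fraction × 100, with
stance percentage defined as its complement so the two always sum to
exactly 100.

**Agreement scoring.** Detected events are matched one-to-one to a
reference train greedily by smallest |Δt|, capped at 0.25 of the median
reference cycle to prevent cross-stride matches; the report gives mean
and max |Δt| as a percentage of the cycle, plus missed and spurious
counts.

## Smoothness metrics

All metrics evaluate a 1-D profile v(t) over a window. The default
profile source is the gyroscope (angular speed is a velocity);
`smoothness.profile_source: accel` switches to the accelerometer, treated
as v(t) directly. SPARC is evaluated on |v| (it expects a non-negative
speed profile); PM and LDLJ use the signed channel.

**SPARC.** The spectrum is computed by FFT after zero-padding to
`zero_pad_factor` × the next power of two (default 4), normalised by its
DC value, and the arc length of (ω/ω_c, V̂) accumulated by trapezoid
(piecewise-linear) summation. The cutoff ω_c is adaptive by default — the
highest frequency at which V̂ still exceeds `amp_threshold` (0.05),
bounded above by 2π·`fc_max` with fc_max = 10 Hz — matching the original
metric definition while honouring the 10 Hz bound appropriate for
walking. `smoothness.fixed_cutoff: true` forces ω_c = 2π·fc_max exactly;
in that mode the spectrum is linearly interpolated at exactly fc_max so
the integral covers [0, ω_c] independent of the FFT grid, which is what
makes grid-refinement comparisons converge. Profiles shorter than 8
samples, or with V(0) = 0, are rejected.

**Peaks Metric.** Equal-value runs are collapsed first so a plateau
strictly above both neighbours counts as one maximum; the metric is the
negative count of interior strict maxima.

**LDLJ.** The second derivative is taken by central second differences on
the interior samples and integrated by trapezoid; v_peak is the maximum
|v| over the window. The leading −ln makes the value decrease as jerk
accumulates. A profile with identically zero jerk (constant or exactly
linear) has no defined LDLJ and is rejected rather than returned as ±∞.

**Table construction.** One record per location × component × scope ×
stride × metric; complete-scope records are computed once per
location/component. Lateral sensors use their own side's strides; the hip
sensor receives both sides' segmentations. Windows shorter than the
8-sample minimum are skipped with a logged warning, never zero-filled.

## Synthetic gait generator

The generator emulates the morphology the detection rule relies on: one
dominant gyroscope-pitch peak per stride at FO (Gaussian bump, width
0.25 × the swing duration) and one impact-like accelerometer-pitch peak
at FS (Gaussian, σ = 30 ms), superimposed on a low-amplitude
stride-periodic cosine that is phase-locked so its per-stride maximum
coincides with the event peak (no competing maxima). The oscillation is
tapered to zero during the standstill lead-in/lead-out (0.8 stride
periods of padding, which also keeps the jitter-free event schedule on
the 100 Hz sample grid). Secondary axes are smaller, slightly shifted
copies so the resultant is genuinely three-dimensional.

Defaults are the healthy-adult conditions the toolkit targets: 1.10 s
stride period, 38.4 % swing fraction, 2 % lognormal (mean-one) per-stride
period jitter, additive Gaussian noise at 5 % of each channel's peak
band-limited at 15 Hz to mimic post-hardware bandwidth, 100 Hz sampling,
foot gyro peak 300 °/s and foot accel impact 25 m/s². The right foot lags
the left by half a stride period. Roughness is injected as
`n_submovements` Gaussian bumps per gait phase (amplitude 20 % of the
channel peak, width 2 % of the phase length, centres at least 3σ apart so
each bump contributes a distinct local maximum).

Non-foot sensors are attenuated (shank 0.6, thigh 0.4, hip 0.25),
phase-shifted (5 % of a stride per proximal segment) copies of the foot
signals; the hip mixes both sides. This is sufficient for
sensor-location comparisons but makes **no claim of biomechanical
fidelity**: passing tests show the pipeline recovers what the generator
encodes (event times, phase structure, relative smoothness), not that it
would handle pathological gait, turning, treadmill walking, soft-tissue
artefact or sensor misalignment, none of which the generator models.

## Statistics

Smoothness values are not normally distributed, so all comparisons are
rank-based: Kruskal–Wallis H (tie-corrected, chi-square approximation,
backed by `scipy.stats.kruskal`; degenerate all-identical input is
defined as H = 0, p = 1), followed by Dunn's z test on mean ranks with
Bonferroni adjustment — the standard Kruskal–Wallis follow-up, staying in
the nonparametric family; pairwise Mann–Whitney is available via
configuration. The chi-square approximation is slightly conservative at
the group sizes used here (the simulated null rejection rate at α = 0.05
with 3 groups of 15 is ≈ 0.045).

The observation unit entering the tests is the per-trial mean per cell
(metric × segment × component × scope) by default; per-stride pooling is
a configuration option. Three report builders mirror the study questions:
complete-signal vs per-stride values per metric and segment; per-cell SD
ranking of the three metrics (winner = lowest SD in the most cells); and
per-component comparison of sensor segments restricted to one metric.
α = 0.05 throughout, configurable.

## Problem sizes

The validation suite uses cohorts of 20 synthetic trials with 6–8 strides
per side, 50–100 random profiles per oracle or invariance check, 20 seeds
per submovement level for the monotonic-response check, and 1000–2000
replicates for null-calibration simulations — sizes at which every
stochastic check is stable across seeds while the whole suite runs in
about a minute.

## Known limitations

- Spatial parameters (step length, velocity) need position data and are
  out of scope; only temporal parameters are computed.
- Event detection is defined for foot-mounted sensors only.
- The adaptive SPARC cutoff makes values comparable only between analyses
  using the same cutoff mode and bound.
- The SD-based "most reliable metric" ranking on synthetic cohorts
  reflects the generator's noise structure; on real recordings the
  winner may differ.
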