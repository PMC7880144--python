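# Methods

This note documents the models and numerical choices behind `ocuload`:
what each stage assumes, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Coordinate and unit conventions

All gaze positions are held internally in degrees of visual angle; pixel
exports are converted on load with a constant pixels-per-degree factor
(`resolution / field_of_view` per axis, e.g. 1920 px / 160° = 12 px/°).
This linear mapping is a small-angle approximation without tangent
correction; for a wide-FOV wearable scene camera the error is negligible
at the eccentricities that matter here, and it keeps the conversion an
exact, invertible closed form. Time is in seconds with t = 0 at the first
sample; phase intervals are half-open `[start, end)` so that a partition
of the time axis assigns every sample to exactly one phase. Missing gaze
or pupil data is NaN, never a sentinel value.

## I-VT classification

Angular speed at sample *i* is the 2-D displacement between samples
*i−h* and *i+h* divided by elapsed time, with *h* = `velocity_window // 2`
(window 3 by default, i.e. a ±1-sample central difference; one-sided at
record edges). Two-point differencing at 100 Hz amplifies position noise
by √2/Δt ≈ 140/s, so the window is configurable. Runs below the 30°/s
threshold lasting ≥ `min_fixation_duration` (60 ms) become fixations;
above-threshold runs become saccades whose amplitude is the distance
between the bounding fixation centroids (run endpoints at the record
edges). Invalid stretches shorter than `max_gap_fill` (75 ms) flanked by
one class are absorbed into it. The 60/75 ms defaults follow common
velocity-filter practice and are exposed in `IVTParams`; the threshold
itself (30°/s) is the standard value for cockpit-distance viewing.
Below-threshold runs shorter than the minimum fixation duration are left
unclassified rather than merged into a neighbour, so events never overlap
and total fixation time is monotone in the threshold.

## Saccadic-intrusion detection

An intrusion is a horizontal excursion during fixation followed by a
return: onset when |x − reference| first exceeds `min_deviation` (0.4°),
where the reference is the mean gaze over the 100 ms preceding onset;
offset at the first sample back within `return_tolerance` (0.4°, the same
value as the deviation threshold) of the reference, provided the return
falls in the 60–870 ms window. Candidates are resolved greedily by onset,
so detections never overlap.

Two choices here were genuinely open:

* **Return is checked against the reference position, both coordinates.**
  The departure criterion is x-only — intrusions are conjugate horizontal
  movements — but requiring the *return* only in x makes a pair of
  ordinary saccades that happen to revisit the same x indistinguishable
  from an intrusion. On synthetic streams this produced a ~30% false
  discovery rate that no threshold could remove. Requiring the gaze to
  return to the same position (x and y within tolerance) removes these
  collisions while leaving horizontal intrusions untouched.
* **An amplitude ceiling** (`max_deviation`, 3° by default) rejects
  excursions too large to be intrusions: intrusions are only a few times
  the size of microsaccades, so multi-degree departures are deliberate
  gaze shifts even if the gaze later returns.

With both rules the detector reaches sensitivity 1.0 and false discovery
≤ 0.02 on 240 s validation streams with 0.05° RMS position noise
(intrusions injected at 0.3/s during sustained fixation at 0.5
fixations/s — an SI-appropriate regime, since intrusions are a fixational
phenomenon).

## MPC — the pupillary spectral index

Per buffer (1 s by default): remove the buffer mean, apply a rectangular
window (Hann optional), take the DFT, form single-sided magnitudes scaled
by 2/N (1/N at DC and Nyquist), and sum the bins whose centre frequency
lies in [1, 5] Hz inclusive. With 1 s buffers at 100 Hz these are exactly
the 1…5 Hz bins, and a bin-centred sinusoid of amplitude A contributes
magnitude A regardless of buffer length — which is what makes the index
comparable across configurations. Mean removal is applied even though the
index is nominally computed on raw dilation samples: without it the DC
bin leaks into 1 Hz under any non-integer-period baseline, and the 1 Hz
bin then measures baseline, not dynamics. Both mean removal and the
window are toggleable. Absolute MPC values are convention-dependent
(scaling, windowing); only orderings and ratios should be compared across
implementations.

Blink gaps shorter than 500 ms are linearly interpolated before the
transform; buffers containing longer (uninterpolated) gaps are flagged
invalid and excluded from means rather than filled.

## Tracking task and inceptor workload

The target is a five-component sum of sines. The default component table
(amplitudes 1.5…0.4°, frequencies 0.054–0.563 Hz, incommensurate) is a
package choice — fully configurable — selected to span the band where
manual pitch tracking is challenging but flyable; the defaults are not
measurements of any particular experiment. Boundaries follow the closed
form `half_width(t) = 5° × 0.8^floor(t/60 s)`.

Duty cycle counts the fraction of samples whose |stick rate| exceeds a
deadband (1°/s default, unstated in the field and config-exposed);
aggressiveness is the RMS stick rate. Stick rate uses the same
central-difference estimator as gaze velocity. Boundary hits are counted
as excursions (contiguous runs with |error| ≥ half-width), not samples.
Events are attributed to boundary steps and windows by onset time; a
trailing partial step is kept and flagged so per-step counts conserve
against whole-trace totals.

## Synthetic generators

`simulate_gaze` draws fixation durations from a gamma distribution
(shape 2, truncated at 100 ms) with mean `1/rate − 30 ms` so the realized
fixation rate matches the profile in expectation; saccades take a fixed
30 ms and relocate gaze by a lognormal amplitude (σ = 0.4, clipped to
1.5–20°) in a uniformly random direction with a centring bias beyond 12°
eccentricity. Intrusions are injected as trapezoidal x-excursions
(0.8–1.5°, 200–600 ms, 20 ms ramps) wholly inside fixations longer than
0.9 s — so at high fixation rates the realized intrusion rate falls below
the profile parameter, a known limitation. Gaussian position noise is
added last.

`simulate_pupil` builds diameter = baseline + slow drift (0.15 mm at
0.02 Hz) + random-phase sinusoids at exactly 1, 2, 3, 4, 5 Hz, each of
amplitude `pupil_band_power`, + white noise. Placing the in-band energy
on the MPC bin centres makes recovery exact in expectation (per-buffer
MPC ≈ 5 × band power), which is what a recovery test needs.

`simulate_pilot_tracking` is a discrete proportional–derivative pursuit
of the target with an integrating plant (`own_rate = plant_gain × stick`)
at 100 Hz. Per boundary step the proportional gain and the stick remnant
scale by `1 + growth × step`; the derivative gain is *not* stepped,
because the discrete derivative term feeds the previous own-pitch
increment back with gain `plant_gain × kd` and stepping it up
destabilises the loop rather than modelling a more aggressive pilot. The
remnant (white noise on the stick, rising with gain) is what makes
per-step duty cycle and aggressiveness increase: a noise-free PD pilot's
stick must track the target derivative regardless of gain, so stick-rate
RMS would otherwise saturate. Divergence (|pitch| > 10⁴°) raises an
error naming the gains.

`simulate_flight` generates phase-wise gaze and pupil plus an altitude
trace at 10 Hz: dives follow a raised-cosine descend-and-recover profile
(smooth, sign-correct vertical speed). With coupling on, the per-second
fixation-rate parameter is `phase rate + coupling × |rate of descent|`,
capped at the feasibility limit — the mechanism behind the inverted-U
co-variation of fixation rate and vertical speed across a dive.

All generators are pure functions of (parameters, seed); child seeds are
spawned from a single `SeedSequence`.

### What the generators do not emulate

Head movement and vestibulo-ocular compensation, smooth pursuit, G-load
effects on the eye, luminance-driven pupil responses, vendor-specific
tracker noise spectra (noise is white Gaussian), and blink dynamics
beyond simple gaps. Detector performance on these streams therefore
bounds performance under ideal recording conditions; it does not certify
behaviour under cockpit vibration or variable lighting, where pupil
measures in particular are known to degrade.

## Statistics

ANOVA uses the explicit between/within sums-of-squares decomposition with
`df = (k−1, N−k)`; the effect size is eta-squared, `SS_between/SS_total`
(equivalently `df₁F / (df₁F + df₂)`). Degenerate inputs are defined
rather than errors: identical groups give F = 0 and effect 0;
zero within-group variance with distinct means gives F = +inf, p = 0,
effect 1. Pairwise tests are uncorrected by default (Holm optional);
Welch's test uses Welch–Satterthwaite degrees of freedom; correlations
are Pearson. Exact p-values are always reported — the α level is the
caller's decision. The alignment utility linearly resamples two
differently-timed series onto the overlap of their spans at the coarser
native resolution.

## Problem sizes

The validation suite uses 60–300 s recordings at 100 Hz (6k–30k samples),
200 random streams for the classifier/oracle equivalence check, and a
360 s four-phase flight with one 80 s dive. These sizes give binomial
standard errors well inside the stated tolerances (e.g. ±5% on ~250
fixation counts) while keeping the whole suite fast enough to run on
every change.

## Known limitations

* The intrusion detector is x-departure-based and cannot represent purely
  oblique intrusions; vertical intrusions are out of scope.
* Realized intrusion rates fall below the profile parameter when fixations
  are short (injection requires a ≥ 0.9 s host fixation).
* MPC absolute values are convention-bound; compare only within one
  configuration.
* The pixel/degree mapping ignores projection nonlinearity; do not use it
  at extreme eccentricities with narrow-FOV cameras.
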