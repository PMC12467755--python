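# Methods

This note documents the models, algorithms, defaults and design choices
behind `speedclimb`, and what the synthetic-data tests do and do not show
about real competition data.

## Coordinate conventions

Wall-plane metres with the y-axis up and the origin at the wall base; time
in seconds from the start of the recording; frames 0-based. Keypoint input
must be sampled near-uniformly in [20, 120] Hz (competition footage is
typically 25–30 Hz); timestamp jitter up to 1 % of the nominal frame
interval is tolerated, beyond that the caller must resample.

## COG computation

Pose data gives joints, not a centre of gravity. Two models are provided:

- `segment_weights` (default for real skeletons): a mass-fraction weighted
  mean of joint y-positions. The built-in table assigns trunk mass to
  shoulders/hips and limb mass to distal joints; it is a documented
  approximation in the spirit of classic segment-inertia tables, not an
  official standard, and can be replaced by explicit weights.
- `midhip`: the unweighted mean of the two hip joints — the fallback when
  only hips are tracked, and the default in the cohort pipeline because
  synthetic skeletons carry the whole-body COG in the hip pair by
  construction.

Velocity and acceleration are central finite differences (one-sided at the
ends); an affine position series differentiates exactly. Optional
Savitzky–Golay smoothing (window 7, order 3) is applied to positions
*before* differencing, never after; it is off by default and recommended
for noisy real data, since double differentiation at 25–30 Hz amplifies
noise strongly.

## End-time detection

The region of interest runs from t₁ (first upward COG crossing of the last
hold's height, sub-frame by linear interpolation) to t₂ (first time the
vertical velocity is negative for k consecutive frames; k = 2 by default —
the number of frames defining "initiation of downward movement" is an
operational choice, logged with every run). Within the ROI the *last*
maximal run of strictly decreasing velocity samples (minimum 3 samples) is
taken as the final decay phase; the second derivative of velocity (double
central differencing, optionally of the smoothed velocity) is scanned for
sign changes there, and the sub-frame time of the last zero crossing is
t_m. An identically zero second derivative (linear decay) is reported as
"no inflection", not as a crossing. Adding a constant to the velocity
leaves t_m unchanged.

The validity filter keeps a run iff |t_m − t_gt| ≤ 0.05·t_gt, boundary
inclusive. On noiseless synthetic runs retention is 100 % and the
estimation error of t_m is far below one frame interval, because the
generator's terminal velocity is an exact cubic in (t − t_m): finite
differences of its (quartic) position preserve the inflection location
exactly, up to float rounding.

## Movement initiation

t₀ is the first time the vertical COG velocity exceeds a threshold
(default 0.2 m/s) and stays above it for 2 consecutive frames, with the
threshold crossing refined sub-frame by linear interpolation between the
bracketing frames (with a zero threshold, the first frame with positive
velocity is returned unrefined). The trace must begin in quasi-rest. The
threshold value is an operational choice — no standard definition exists —
and is logged with every run. h₀ is the COG height at t₀, so the first
split-time gap uses the athlete's actual starting COG height, not the wall
base.

## Split times and section statistics

Crossings of all 20 hold heights give Δtᵢ, Δhᵢ, Δt̂ᵢ = Δtᵢ/Δhᵢ anchored at
(t₀, h₀); t_r = t₀ − t_s and t_j = t_gt − t₂₀. The Δt sum telescopes to
t₂₀ − t₀ by construction, and Δt̂ is invariant to a global time shift.
Crossing-time precision is limited by the sampling grid (about half a
frame interval), which the 25–30 Hz frame rate of competition footage also
imposes on real data.

The wall sections default to start = holds 1–5, middle = 6–13,
end = 14–20 (the 5→6 transfer marks the move into the middle section and
the last ~5 m form the end section); the partition is configurable since
no numeric boundary is standardised. Per-hold summaries use type-7
(linear-interpolation) quartiles and standard boxplot fences at
Q1 − 1.5·IQR and Q3 + 1.5·IQR; section aggregates pool member-hold
observations, i.e. hold means enter weighted by their counts. The
height-binned velocity profile (default 5 cm bins) averages within each
run first and then across runs, so fast and slow runs weigh equally.

No official hold-height map ships with the package: `example_hold_map()`
is a clearly non-official, evenly spaced stand-in (1.9 m to 15 m); real
analyses must supply the route's map.

## Sinusoidal limb model

Limb velocity signals are fitted to v(t) = A·sin(ωt + φ) + C by
least squares over the window from the first to the last detected velocity
peak (peaks = local maxima with prominence ≥ 0.5·sd of the signal, ties to
the earlier index), which excludes the irregular run edges. Starting
values: C₀ = mean, A₀ = √2·sd (exact for a pure sinusoid), φ₀ = 0, and ω₀
from one of two strategies:

- `hilbert`: the mean instantaneous frequency, f(t) = (1/2π)·dφ/dt of the
  unwrapped analytic-signal phase, with 10 % of samples trimmed at each
  edge before averaging (analytic-signal edge artifacts dominate short
  windows at these frame rates);
- `fft` (default): the dominant frequency of the mean-centred signal,
  zero-padded to 0.02 Hz bin spacing, DC excluded, ties to the lower bin.

For the `fft` strategy the start frequency is refined over a grid of 41
candidates spanning ±20 % around the dominant frequency. Each candidate is
scored by the *exact* conditional least-squares SSR — at fixed ω the model
a·sin(ωt) + b·cos(ωt) + C is linear, so the profiled SSR is a closed-form
solve — and the three best candidates are polished with
Levenberg–Marquardt at tight tolerances; the minimum-SSR solution wins.
This screening gives the same refinement as locally optimising every grid
point at a fraction of the cost, and the optimizer can never end worse
than its starting values. Results are canonicalised to A ≥ 0, ω > 0,
φ ∈ [−π, π).

Diagnostics: R² = 1 − SSR/SST (undefined and raised as an error for
constant data); the mean peak distance, pairing each data peak with the
nearest closed-form maximum of the fitted sinusoid (each data peak matched
once — "related peaks" has no standard definition, nearest-in-time is the
package's choice); the FFT dominant frequency; and asymptotic standard
errors from the Gauss–Newton covariance. With noise of sd σ on a tone of
amplitude A, the population R² is 1 − σ²/(σ² + A²/2), which noisy-recovery
tests verify at the cohort's noise levels.

The limb signal defaults to the 2-D speed magnitude of the ankle/wrist
keypoint (switchable to the vertical component); whether speed or a
component better reflects limb coordination is genuinely open, so both are
supported and the choice is logged.

## Phase synchronicity

Signals are mean-centred and band-passed to 0.5–3 Hz — a band that covers
observed limb cadences with margin — using an order-4 Butterworth applied
forward-backward (zero phase, so phase differences are preserved; the
effective magnitude response is the squared order-4 design). Phases are
the angles of the Hilbert analytic signals; Δφ is wrapped to [0, 2π) and
μ_π = mean |Δφ − π| ∈ [0, π]. μ_π is exactly symmetric in its arguments
because |Δφ − π| is invariant under Δφ → 2π − Δφ. An optional window
argument restricts μ_π to an excerpt (e.g. the middle wall section);
cohort reporting uses the full run by default.

## Synthetic data

The generator encodes the study conditions the analysis targets:

- 30 Hz sampling by default (configurable 25–30 Hz and beyond);
- normalised split-time means (0.39, 0.38, 0.45) s/m for the start,
  middle and end sections, with optional per-section Gaussian scatter at
  (0.028, 0.033, 0.035) s/m — scatter magnitudes are treated as scales
  only, no distributional claim is made;
- reaction time 0.13 s (a cohort median) and jump time 0.45 s;
- limb speeds A·sin(2πft + φ) + C with foot cadence ~1.8 Hz, A = 1.2 m/s,
  C = 1.8 m/s (C > A keeps noiseless speeds positive so integrated limb
  tracks are consistent with the planted sinusoid), anti-phase left/right
  feet, and white measurement noise;
- hand-track occlusion at a configurable rate (never the first/last frame,
  never the feet);
- a COG trajectory built as a monotone PCHIP spline through the hold
  heights at the planned crossing times, a rest segment before t₀, and a
  terminal segment whose velocity is the cubic α·u³ + β·u + v_m in
  u = t − t_m with α, β < 0: strictly decreasing, with its single
  inflection exactly at u = 0 and a zero crossing (apex, then descent)
  shortly after, so the end-time ROI is always well defined.

Cohorts draw end times uniformly on 4.7–6.0 s (the elite-male range) and
foot cadence conditionally Gaussian given the end time: a linear mean
whose slope is solved in closed form so the population Pearson correlation
equals the planted value, and a linearly increasing sd so slower runs show
more cadence scatter. Hand cadence is drawn independently of end time and
acts as a planted-null feature. Each run's randomness comes from a
substream keyed on (seed, run index), making generation order-independent
and byte-reproducible.

What passing these tests shows: the estimators recover exactly the
structure they assume, at realistic magnitudes, sampling rates and noise
levels, and the pipeline propagates a planted effect end to end without
attenuation or leakage. What they do not show: robustness to pose-detector
error structure (non-white, occlusion-correlated), camera-motion residues,
non-sinusoidal hand movement with hold contact plateaus, or route-specific
COG paths — real hands, in particular, violate the mono-frequent model by
design, which is why hand fits may legitimately fail and become missing
cells rather than sentinel values.

## Cohort reporting

The default filter mirrors an elite-male analysis subset: sex = male,
start technique = "Tomoa Skip", end time strictly below 6 s. End time is
the scoreboard time t_gt where available (the estimate t_m is its
validation, not its replacement; configurable). Correlations are Pearson r
with two-sided p-values from the t distribution on n − 2 degrees of
freedom, computed pairwise per feature (missing cells dropped per pair,
per-cell n reported); raw p-values are reported by default, with an
optional Holm step-down flag. Runs that fail any per-run stage are logged
and skipped, never aborting the cohort; runs failing the 5 % validity
filter are excluded from cohort statistics and listed in the validity
report.

## Problem sizes and determinism

Test and acceptance runs use cohorts of 10–30 runs for structural checks
and a single 321-run cohort for planted-correlation recovery — the size of
the filtered elite-male subset the analysis design targets. All randomness
flows from named substreams of a single integer seed; repeated runs with
the same seed produce byte-identical CSV output (output directories are
only timestamped when not specified explicitly).

## Known limitations

- The COG weighting scheme is a stand-in; anthropometric fidelity was not
  a goal.
- Sub-frame estimates (crossings, t₀, t_m) are linear interpolations;
  their accuracy degrades with curvature at 25 Hz.
- The sinusoid model is mono-frequent by design; multi-frequency movement
  (hands, errors/slips) yields low R² rather than a better model.
- The permutation/Fisher checks treat runs as independent, although real
  cohorts repeat athletes; athlete-level clustering is not modelled.
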