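# speedclimb

Kinematic performance analysis for speed climbing, from 2-D keypoint
trajectories to cohort-level coordination statistics.

In competitive speed climbing, athletes race up a standardised 15 m wall
with 20 hand holds; elite runs finish in under 6 s. Given per-joint
wall-plane trajectories (e.g. from a pose-estimation system), this package
computes the quantities that characterise a run and a cohort:

- **End-time detection.** The buzzer touch is not directly observable in
  keypoint data. Within a region of interest from the centre of gravity
  (COG) crossing the last hold height (t₁) to the onset of downward body
  movement (t₂), the touch time t_m is the inflection of the last decay
  phase of the vertical COG velocity v_c(t):

  d²v_c/dt²(t_m) = 0, t₁ < t_m < t₂.

  A run enters the analysis dataset only if |t_m − t_gt| ≤ 0.05 · t_gt,
  where t_gt is the documented scoreboard time.
- **Split times.** With t₀ the movement-initiation time and tᵢ the first
  upward COG crossing of hold height hᵢ: Δtᵢ = tᵢ − tᵢ₋₁,
  Δhᵢ = hᵢ − hᵢ₋₁, and the height-normalised split Δt̂ᵢ = Δtᵢ/Δhᵢ (s/m);
  plus reaction time t_r = t₀ − t_s and jump time t_j = t_gt − t₂₀.
- **Limb coordination.** Limb (ankle/wrist) velocity signals are fitted by
  least squares to a mono-frequent sinusoid v(t) = A·sin(ωt + φ) + C, with
  frequency initialisation either from the Hilbert instantaneous frequency
  or from the FFT dominant frequency refined over ±20 %. Goodness of fit
  (R² = 1 − SSR/SST), mean data-to-model peak distance and the dominant
  frequency summarise each limb.
- **Phase synchronicity.** Instantaneous phases φ(t) come from the analytic
  signal z(t) = v(t) + i·H(v). The index μ_π = mean |Δφ(t) − π| of the
  wrapped phase difference of the two feet is 0 for perfect anti-phase
  (alternating) motion and π for in-phase motion.
- **Cohort reporting.** Filtering (sex, start technique, end-time cap),
  Pearson correlations of end time against each coordination metric with
  two-sided p-values, and foot-cadence distributions per end-time interval.

Because competition keypoint data cannot be redistributed, the
`speedclimb.synthetic` module generates runs and cohorts with full ground
truth: monotone COG climbs through configurable split profiles, terminal
velocity decays with a known inflection, sinusoidal limb signals with
anti-phase feet, hand occlusion gaps, and cohorts with a planted
end-time/cadence correlation.

## Worked example

```python
import speedclimb as sc
from speedclimb.synthetic import SyntheticRunConfig, assemble_run

cfg = SyntheticRunConfig()                       # 30 Hz, anti-phase feet at 1.8 Hz
tracks, meta, truth = assemble_run(cfg, seed=42)
row, profile = sc.analyze_run(tracks, meta, cfg.hold_map)
print(f"tm={row['tm']:.3f}s tgt={row['tgt']:.2f}s valid={row['valid']}")
print(f"tr={row['tr']:.3f}s tj={row['tj']:.3f}s")
print(f"right foot: R2={row['right_foot_r2']:.3f} "
      f"f={row['right_foot_dominant_freq']:.2f}Hz mu_pi={row['mu_pi_feet']:.3f}")
```

prints

```
tm=6.274s tgt=6.27s valid=True
tr=0.124s tj=0.445s
right foot: R2=1.000 f=1.80Hz mu_pi=0.000
```

The estimated buzzer time agrees with the planted scoreboard time (so the
5 % validity filter passes), the reaction and jump times match the
configured 0.13 s / 0.45 s, the noiseless foot signal is explained
perfectly by the sinusoid at the planted 1.8 Hz cadence, and μ_π = 0
reflects exact anti-phase foot motion.

The statsmodels-style model object is available directly:

```python
from speedclimb import SinusoidModel
res = SinusoidModel(v, times=t).fit(strategy="fft")
print(res.summary())   # estimates, standard errors, R2, peak distance
res.plot()             # data, fit and residuals (requires matplotlib)
```

A CLI wraps the pipeline: `speedclimb generate`, `speedclimb analyze-run`,
`speedclimb analyze-cohort`, `speedclimb report` (see `--help`).

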