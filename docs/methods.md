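# Methods

## The measurement model

A repeated-measures running protocol is emulated: each of `n_participants`
runners completes `n_days` testing days; on every day and on each surface the
two analyzed runs (protocol labels 1 and 3, the outbound runs of a 140 m
track) are recorded, and each run is processed twice against two different
sensor-to-segment calibration trials.  A "measurement" is therefore indexed
by (participant, day, surface, run, calibration).

The synthetic generator models every joint-angle channel as a fixed periodic
template waveform plus additive offsets drawn once per level of the design:

    angle(t) = template(phase(t)) + u_runner + u_day + u_run + u_calibration
               + u_stride(t)

with u_x ~ N(0, sigma2_x) independent across levels and signals.  Offsets act
on the waveform as a whole, so every discrete feature extracted downstream
(initial value at 0 % of the cycle, signed extremum in the 0–40 % stance
window) inherits them unchanged.  The population intraclass correlation of a
feature is then exactly

    ICC = sigma2_runner / (sigma2_runner + sigma2_error),

where `sigma2_error` sums the components that differ between the two
measurements of a comparison pair:

| comparison    | error components                                         |
|---------------|----------------------------------------------------------|
| between-day   | day + run + calibration + stride/n̄                       |
| within-day    | run + stride/n̄                                           |
| calibration   | calibration only (the two copies share all stride data)   |

`stride/n̄` is the variance of run-averaged stride noise over the n̄ cycles
actually averaged (n̄ = 40 under the defaults); `truth_icc` takes n̄ as an
argument because the generator cannot know the downstream trim.  Between-day
pairs use run 1 under calibration 1 of each day, and since each day's
calibration is an independent performance, the calibration component appears
in the between-day error.

Day, run and calibration effects are drawn independently per surface, so the
two surfaces are independent replicates of the same design.

### Default parameters

Per-signal variance components (deg²) are illustrative, not fitted — chosen
so that (a) between-day error variance is roughly four times within-day error
variance, making between-day absolute differences about twice the within-day
ones, and (b) the implied ICCs fall in the bands reported for IMU-based
running kinematics (sagittal knee excellent, frontal ankle poor-to-moderate
between days).  How much of the between-day error is runner-internal versus
technical is not separately identified by this design; the split across day /
run / calibration components is a modelling choice.

| signal             | runner | day | run | calibration | stride |
|--------------------|-------:|----:|----:|------------:|-------:|
| hip_flexion        | 16.0   | 1.2 | 0.4 | 0.3         | 4.0    |
| hip_abduction      | 6.0    | 1.8 | 0.5 | 0.45        | 3.0    |
| knee_flexion       | 20.0   | 1.0 | 0.5 | 0.1         | 4.0    |
| ankle_dorsiflexion | 8.0    | 2.5 | 0.5 | 0.8         | 4.0    |
| ankle_eversion     | 6.0    | 3.0 | 0.6 | 1.0         | 4.0    |

Other defaults: 17 runners, 5 days, surfaces asphalt/woodchip, 48 strides per
run (46 detectable cycles, 40 after trimming), 240 Hz sampling; self-selected
speed N(3.47, 0.30²) m/s between runners with 0.05 m/s timing-gate noise per
run; stride frequency N(1.40, 0.10²) Hz between runners with 0.035 Hz
run-to-run deviation (implying SF reliability ≈ 0.89 rather than a degenerate
1.0); AP-position amplitude 0.4 m.  Stride-period jitter (SD as a fraction of
the period, default 0 so that exactness tests are exact; 1 % exercises
segmentation robustness) perturbs individual stride durations.

Templates are baselines plus raised-cosine bumps with compact support, placed
so the nine features of the pure template take realistic values (IKF 7.53,
PKF 42.53, IHF 34.77, PHA −9.42, IAI −7.47, PAE 11.83 deg; adduction and
inversion negative under the ISB-style sign convention, so the hip-adduction
peak is a signed minimum).  Bump supports exclude phase 0, which makes the
0 %-of-cycle feature of the template analytic.

### What the generator does and does not emulate

It reproduces the design structure, the hierarchical variance decomposition,
periodic foot kinematics with maxima exactly on cycle boundaries (rounded to
sample resolution), paired calibration copies sharing stride data, timing-gate
speed noise, and stride-timing variability.  It does **not** model soft-tissue
artefact, sensor drift, waveform *shape* changes between measurements (offsets
shift curves rigidly, so initial and peak features of one signal are perfectly
correlated — real data decouple them), non-Gaussian or heteroscedastic errors,
or trunk/arm channels.  Passing tests therefore validate the statistical
machinery and its implementation, not the field behaviour of any particular
sensor system.

## Segmentation and normalization

Cycle boundaries are local maxima of the right-foot AP position with a
minimum separation of 0.4 s (below any plausible running stride period) and a
relative prominence of 10 % of the signal range.  No initial-contact event
detection is attempted; cycles intentionally begin slightly before foot
contact.  A symmetric trim removes `n_trim` = 3 cycles from each end of the
run (the acceleration/deceleration transients), reproducing ~40 analyzed
cycles per run.  Cycles whose duration deviates from the run median by more
than 3 robust standard deviations (1.4826 × MAD, floored at 20 ms so ordinary
stride-timing variation survives) are dropped before averaging; a plain SD
was rejected because a single false maximum inflates it enough to mask
itself.  Each retained cycle is resampled by linear interpolation (shape
preserving, no overshoot) onto 101 points inclusive of both boundaries;
averaging is pointwise; stride frequency is the reciprocal mean retained
duration.

Because the percent grid lands between samples, peak features of a curved
waveform carry a small interpolation bias (≈0.05 deg at 240 Hz).  The bias is
constant within a runner at fixed stride period, so it cancels from all
within-runner comparisons; exactness tests assert initial features absolutely
and peak features via within-runner differences.

## Reliability statistics

ICC(A,1) — the absolute-agreement, single-measurement form of the two-way
random-effects model — is computed from the ANOVA mean squares of each
n×2 pair matrix; negative estimates are reported as computed, never clipped,
and a zero-total-variance matrix is flagged as undefined rather than forced
to 1.  SEM = √MSE and MDC = 1.96·√2·SEM exactly.  Aggregation over the five
pairs uses the middle order statistic and [min, max]; per-pair confidence
intervals are not computed (only the median and range are reported).
Within-day differences for day pair (d, d+1) are attributed to day d; the
day-pair set for n days is the consecutive pairs plus an (n, 2) closure so
every day contributes equally to the median.  Missing participants are
excluded listwise per pair and logged.  Running speed and stride frequency
are excluded from the calibration design: reprocessing cannot change gate
timings or cycle durations, so their calibration ICC is degenerate by
construction.

## Mixed model

The difference matrix stacks |Δ| of one joint-angle variable, of speed and of
stride frequency for every participant × day pair × surface.  The
random-intercept model is estimated by REML (statsmodels `MixedLM`);
inference uses normal-approximation Wald intervals and p-values — the exact
degrees-of-freedom method of the original GUI analysis is not recoverable, so
the simplest defensible approximation is used and documented.  Predictors
enter untransformed (deg per m/s, deg per Hz; surface coded asphalt 0,
woodchip 1 so the surface coefficient is woodchip − asphalt), but internally
each predictor column is scaled to unit SD for optimizer conditioning (SF
differences live on a ~0.03 Hz scale) and estimates are unscaled afterwards;
the optimizer falls back through lbfgs → bfgs → powell → nm.  Constant
predictor columns are dropped and reported as NaN coefficients (a constant
cannot predict anything; this also covers single-surface designs).  Marginal
R² follows Nakagawa–Schielzeth: var(Xβ̂) / (var(Xβ̂) + σ²_intercept +
σ²_residual).  A random-intercept variance estimated at the boundary 0 is
flagged `singular` but results are still returned.

## Numerical and design choices

- One `numpy` generator seeded from `SimulationConfig.seed` drives all draws
  in a documented order (runner-level arrays first, then per-run draws in
  participant → surface → day → run order); identical seeds give bit-identical
  cohorts and reports.
- Variance components are keyed by *signal*, not by discrete variable: an
  offset shifts the whole waveform, so the initial and peak features of one
  signal necessarily share components; a per-variable parameterization could
  not be realised by waveform shifts.
- Stride periods are rounded to integer samples so that true boundaries lie
  exactly on samples and noise-free segmentation recovery can be asserted at
  sample resolution.
- The feature-level fast path (`simulate_feature_table`) draws the identical
  offset model without waveform synthesis, entering stride noise as its run
  average; Monte-Carlo studies (ICC recovery over hundreds of cohorts) use it
  because the waveform path adds only deterministic, separately-tested
  plumbing.
- `icc_precision` reports half the central 95 % spread of the simulated
  sampling distribution of ICC(A,1) — a simulation analogue of the
  closed-form precision used for reliability-study sample-size planning
  (≈0.195 at n = 17, k = 2, true ICC 0.8).
- Problem sizes in tests and the acceptance script (500 feature-level cohorts,
  200 mixed-model replicates, 1000 oracle matrices, 3-runner segmentation
  cohorts) were chosen as the smallest sizes at which the Monte-Carlo error of
  each check is comfortably below its assertion band.

## Known limitations

- Between-day and calibration reliability cannot be separated from run-level
  effects with fewer than two runs per calibration per day; the generator
  inherits this confound from the design it emulates.
- The analytic SF reliability neglects the sample-resolution quantization of
  the stride period (≈0.008 Hz steps at 240 Hz — small against the 0.035 Hz
  run-to-run deviation, but not zero).
- Proprietary motion-capture exports are not parsed; `io.convert_mvnx` is a
  documented stub describing the expected channel mapping onto the long-form
  session CSV schema.
- With offsets as the only error mechanism, every variable of a signal shares
  one reliability structure; findings that depend on initial-vs-peak
  decoupling cannot be studied on this generator.
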