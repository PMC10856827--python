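# gaitrel

Test–retest reliability of wearable-IMU running kinematics.

Inertial motion-capture suits make it possible to measure 3D lower-extremity
joint angles during unconstrained, over-ground running — but how repeatable
are those measurements between two runs on the same day, between days, and
between two sensor calibrations of the *same* run?  `gaitrel` implements the
full analysis pipeline for that question, for biomechanists and movement
scientists who work with repeated-measures kinematic field data:

1. **Segmentation** — running gait cycles are delimited by successive maxima
   of the right foot's anterior–posterior position relative to the pelvis,
   run transients trimmed, each cycle time-normalized to 101 points
   (0–100 % of the gait cycle) and averaged to one waveform per run.
2. **Discrete features** — nine joint-angle variables (initial hip flexion
   IHF, initial/peak hip ab-/adduction IHA/PHA, initial/peak knee flexion
   IKF/PKF, initial/peak ankle dorsiflexion IAD/PAD, initial ankle inversion
   IAI, peak ankle eversion PAE) read off the averaged waveform: *initial* at
   0 % of the cycle, *peak* as the signed extremum within the approximated
   stance phase (0–40 %); plus running speed (RS, timing gates) and stride
   frequency (SF).
3. **Reliability** — for each variable, surface and comparison type
   (between-day, within-day, calibration), five measurement pairs each feed a
   two-way ANOVA from which the absolute-agreement single-measure intraclass
   correlation is computed:

   ```
   ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
   SEM      = √MSE
   MDC      = 1.96 · SEM · √2
   ```

   aggregated as median [min, max] across the five pairs, and labelled
   poor / moderate / good / excellent (cut-offs 0.5 / 0.75 / 0.9, with a
   conservative downgrade when the minimum ICC falls in a lower category
   than the median — the categories map onto the colour coding used in
   published reliability tables).
4. **Error sources** — a 170-row difference matrix per variable (17 runners ×
   5 day pairs × 2 surfaces) of absolute between-day differences feeds a
   random-intercept linear mixed model (REML) with the between-day speed
   difference, stride-frequency difference and surface as fixed effects,
   reported with Wald 95 % intervals and the Nakagawa–Schielzeth marginal R².

Because raw suit recordings require proprietary reprocessing, the package
ships a first-class **synthetic cohort generator** (`gaitrel.synth`) that
emulates the study design — 17 runners × 5 days × 2 surfaces × 2 analyzed
runs × 2 calibration copies, ~40 analyzable cycles per 140 m run at 240 Hz —
with additive runner-, day-, run-, calibration- and stride-level offsets, so
the true ICC of every variable is known analytically and every stage of the
pipeline can be verified against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
cohort (bulky intermediates go to `scratch/`, tables to `results/`):

```
python analysis/01_simulate.py --seed 1   # 680 session CSVs + ground truth
python analysis/02_segment.py             # cycles, trimming, 101-point averaging
python analysis/03_extract_features.py    # 680-row feature table
python analysis/04_reliability.py         # ICC / SEM / MDC tables
python analysis/05_association.py         # difference matrices + mixed models
python analysis/06_icc_precision.py       # design-planning utility
```

With seed 1, segmentation retains exactly 40 cycles per run, and the
reliability stage prints (excerpt):

```
median ICC by variable (rows) and comparison type x surface:
                between_day          within_day           calibration
                asphalt woodchip     asphalt woodchip     asphalt woodchip
IHF                0.76     0.82        0.95     0.95        0.98     0.97
IKF                0.93     0.94        0.98     0.97        1.00     1.00
IAI                0.54     0.48        0.93     0.94        0.87     0.92

mean absolute differences: between-day 1.63 vs within-day 0.74 (ratio 2.21)
median |estimated - analytic ICC| = 0.021
```

Read: with the default variance components, between-day agreement is clearly
lower than within-day agreement (absolute between-day differences are about
twice the within-day ones), the estimated median ICCs track the analytic
values implied by the generator's variance components to ~0.02, and the
frontal-plane ankle signal (IAI/PAE) — given the largest day-to-day and
calibration variance — lands in the poor-to-moderate between-day band, while
sagittal knee flexion stays excellent.  The planning utility reports an
expected 95 % half-width of **0.195** for an ICC of 0.8 estimated from 17
runners and paired measurements, which is the precision regime in which a
5-day repeated-measures design operates.

Library use without the scripts:

```python
from gaitrel import SimulationConfig, run_pipeline
report = run_pipeline(SimulationConfig(seed=1))
print(report.icc_table.head())
```

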