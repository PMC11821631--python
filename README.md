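# tmgkit

Analysis pipeline for electrically evoked muscle twitches: peak twitch
torque (Pt) from a dynamometer channel and tensiomyographic (TMG) radial
muscle-belly displacement from the same stimulus, with the statistics used
to decide whether a muscle is *potentiated* or *fatigued* and whether the
displacement parameters can diagnose that state.

It is written for exercise physiologists and sports scientists who record
stimulus-triggered torque/displacement sessions (or want to simulate
them) and need the full chain — signal extraction, test–retest
reliability, longitudinal inference, and diagnostic accuracy — as
reproducible, tested code rather than spreadsheet steps.

## What it computes

**Signal extraction.** Voluntary contractions are summarized by the MVIC:
the highest centered rolling median (default window 501 samples) where
torque exceeds a 20 Nm floor. Each twitch is located by the stimulator's
trigger channel; the torque trace is low-pass filtered (zero-phase 4th-order
Butterworth, 15 Hz cutoff) and Pt is the post-stimulus peak above the
pre-stimulus baseline. From the displacement trace the pipeline extracts
the maximal displacement Dm (first qualifying local peak), the delay time
Td (stimulus → 10 % of Dm) and contraction time Tc (10 % → 90 % of Dm),
with sub-sample interpolation of the threshold crossings.

**Derived rates of displacement** (Td, Tc in ms):

    Vc0–10%  = 0.1·Dm/Td·1000        Vc0–90%  = 0.9·Dm/(Td+Tc)·1000
    Vc10–90% = 0.8·Dm/Tc·1000        Vcnorm   = 0.8/Tc·1000

and the fatigue index FI = 100·(MVIC_first − MVIC_last)/MVIC_first.

**Reliability.** For the two pre-exercise baselines, per parameter: paired
t-test for systematic bias, bias-corrected Hedges' g (standardized by the
average SD, J = 1 − 3/(4(n−1)−1)), ICC(A,1) (two-way, absolute agreement,
single rating) with an F-based 95 % CI, and the absolute chain

    SEM = SD·√(1 − ICC)        MDC = SEM·1.96·√2

with SD and the grand mean pooled over both baselines.

**Inference.** Tukey screening at 3×IQR, neighbor-mean interpolation of
interior missing values, one-way within-subject RM-ANOVA with
Greenhouse–Geisser correction, Bonferroni-corrected post hocs against
baseline, and Pearson correlation of percent changes, all with the
conventional magnitude bands.

**Diagnostics.** A subject whose change from baseline exceeds a
parameter's MDC is potentiated (increase) or fatigued (decrease). Each
displacement parameter is scored as an index test against the Pt
reference: 2×2 tables, Sn/Sp/PPV/NPV with exact Clopper–Pearson CIs,
diagnostic effectiveness DE = Sn·prev + Sp·(1−prev), Youden's index
YI = Sn + Sp − 1, and a rank-based AUROC on percent changes.

**Synthetic sessions.** A calibrated generator produces full cohorts
(bi-exponential twitch waveforms, trigger pulses, MVIC traces) whose
torque trajectory rises +44.1 % after the first exercise set, falls to
−32.9 % after the last, and recovers to −26.4 % at 15 min post — with the
displacement channel attenuated by a configurable coupling factor. Every
downstream stage is testable without any recorded data.

## Worked example

```python
from tmgkit import SimulationConfig, simulate_cohort, extract_cohort
from tmgkit.metrics import add_derived_columns
from tmgkit.reliability import reliability_table
from tmgkit.diagnostics import diagnostic_table

cfg = SimulationConfig(n_subjects=16, seed=42)
params = add_derived_columns(extract_cohort(simulate_cohort(cfg)))
rel = reliability_table(params)
print(rel[["parameter", "icc", "sem", "sem_pct", "mdc", "mdc_pct"]]
      .round(2).to_string(index=False))
```

```
parameter  icc  sem  sem_pct   mdc  mdc_pct
       Pt 0.99 0.62     3.13  1.72     8.68
       Dm 1.00 0.08     2.38  0.23     6.60
       Td 0.94 0.68     3.25  1.87     8.99
       Tc 0.87 0.77     3.60  2.13     9.98
   Vc0_10 0.99 0.83     4.97  2.30    13.77
   Vc0_90 0.99 3.33     4.49  9.23    12.44
  Vc10_90 0.98 7.14     5.44 19.78    15.08
   Vcnorm 0.88 1.34     3.54  3.72     9.81
```

Each row is one twitch parameter's test–retest report: an ICC near 1
means nearly all between-trial variance is between subjects; the MDC
column is the smallest change (in native units) distinguishable from
measurement noise at 95 % confidence — e.g. a Pt change must exceed
1.72 Nm before this cohort's measurement would call it real.

```python
diag = diagnostic_table(params, rel)
post1 = diag[diag.timepoint == "Post1"]
print(post1[["parameter", "sn", "sp", "de", "yi", "auroc"]]
      .round(2).to_string(index=False))
```

```
parameter   sn  sp   de    yi  auroc
       Dm 0.93 0.0 0.88 -0.07   0.00
       Td 0.00 1.0 0.06  0.00   1.00
       Tc 0.00 1.0 0.06  0.00   0.67
   Vc0_10 0.60 0.0 0.56 -0.40   0.00
   Vc0_90 0.60 0.0 0.56 -0.40   0.00
  Vc10_90 0.60 0.0 0.56 -0.40   0.07
   Vcnorm 0.00 1.0 0.06  0.00   0.33
```

At 1 min post-exercise most subjects are fatigued by the torque
reference; with the default displacement coupling of 0.5 the
amplitude-linked parameters (Dm, Vc) detect only part of that, and the
timing parameters (Td, Tc, Vcnorm), which the default generator holds at
baseline, detect none — the mechanism by which an attenuated
displacement response destroys diagnostic accuracy.

The same analysis is available as a CLI (`tmgkit run --seed 42 --out
run/`), with per-stage subcommands `simulate`, `extract`, `derive`,
`analyze` and `diagnose` operating on CSV files.

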