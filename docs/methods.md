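# Methods

This note documents the models, conventions and numerical choices behind
tmgkit, in the order the pipeline runs.

## Twitch waveform model

Both the torque and the displacement of a single evoked twitch are
modelled as a delayed bi-exponential,

    w(t) = A · (e^{−(t−d)/τ_decay} − e^{−(t−d)/τ_rise}),   t ≥ d,

rescaled so the sampled maximum equals the amplitude `A` (Nm for torque,
mm for displacement), with `τ_decay > τ_rise > 0` (ms) and onset delay
`d ≥ 0` (ms). This is the standard parsimonious twitch shape: a single
rise and a single decay process, analytic peak time
`t* = d + τ_rise·τ_decay/(τ_decay−τ_rise)·ln(τ_decay/τ_rise)`, and a
monotone rise through the 10 %/90 % thresholds, so Dm, Td and Tc of a
synthetic twitch are checkable against closed-form/dense-grid references.
Rescaling is by the sampled rather than the continuous maximum so that the
generated trace itself satisfies the amplitude contract exactly at any
sampling rate.

`shape_from_targets` inverts the family: given target Td and Tc it fixes
the decay ratio (default `τ_decay/τ_rise = 3`), solves the normalized
curve's 10 %/90 % crossings once by bisection, scales `τ_rise` so the
10→90 % span equals Tc, and sets the onset delay so the 10 % crossing
lands at Td (clipped at zero, so extremely short target delays extract
slightly long). Torque twitches use fixed timing (`τ_rise` 25 ms, ratio
3, onset 10 ms; analytic time-to-peak ≈ 75 ms, typical of knee-extensor
twitches) because only the torque *amplitude* enters the analysis.

## Session generator

The generator's defaults are the study conditions the pipeline is
validated under: 16 subjects, 1000 Hz sampling, a schedule of two
baselines (Pre1, Pre2), seven exercise sets and nine recovery timepoints
(Post0–Post15, minutes after exercise).

* **Baselines.** Per-subject parameters are drawn from truncated normals
  with population means/SDs Pt 19.47 ± 8.49 Nm, Dm 3.06 ± 1.86 mm,
  Td 20.45 ± 4.21 ms, Tc 21.64 ± 2.41 ms. (The second pre-exercise
  column differs negligibly; one set of anchors is used.) Truncation
  keeps amplitudes positive and timing physiological; the Td SD uses the
  narrower of the two printed baseline SDs because the wider one is
  dominated by a single outlying session.
* **Trajectory.** A deterministic multiplier `m(t)` scales each subject's
  torque amplitude: 1 at both baselines, 1.441 after the first set,
  declining linearly in set number to 0.671 at the last set, then
  recovering linearly in minutes to 0.736 at 15 min. The displacement
  amplitude uses `1 + c·(m − 1)` with coupling `c ∈ [0, 1]`
  (default 0.5), encoding the finding that radial displacement responds
  less to potentiation/fatigue than torque does. Timing parameters (Td,
  Tc) are held at each subject's baseline: the default generator studies
  the amplitude mechanism only, so timing-derived sensitivities are
  structurally zero — a deliberate simplification, not a claim about
  muscle physiology.
* **Noise.** Trial-to-trial variation is multiplicative lognormal
  (unit median) with coefficient of variation `within_subject_sd`
  (default 0.03, giving baseline ICCs in the high 0.9s like the real
  data), applied to amplitudes and timing; traces additionally carry
  additive Gaussian noise (0.05 Nm, 0.005 mm). Multiplicative noise
  keeps amplitudes positive and makes "noise-free" (`within_subject_sd
  = 0`) an exact retest.
* **MVIC / fatigue index.** Each subject performs 60 contractions
  (5+5+10·5); plateau torque declines linearly from a subject-specific
  start (~200 Nm) so that FI = 100·(first−last)/first follows
  N(39.8, 11.5²) truncated to [0, 100].
* **Determinism.** All draws flow from one `numpy` Generator seeded by
  `config.seed`; identical configs are bit-identical.

What the generator does **not** emulate: calcium-kinetics or fibre-type
mechanisms, electrode/sensor placement artifacts, drift within a session,
sex differences, or any change in contraction *speed* over the protocol.
Passing tests therefore demonstrate that the analysis chain recovers what
the generator encodes — amplitude trajectories under measurement noise —
not that it would detect every physiological signal in real recordings.

## Extraction conventions

* **MVIC.** Centered rolling median, full windows only (no edge
  shortening), maximum over window centers whose torque exceeds the
  20 Nm floor; window 501 samples ≈ 0.5 s at the default rate. A trace
  never above the floor yields NaN (missing flag), not an exception.
* **Filtering.** Zero-phase (forward–backward) application of the
  4th-order 15 Hz Butterworth design, chosen to preserve peak timing;
  the effective magnitude response is the square of the single-pass
  response. Filtering before peak-picking can overshoot a few percent
  near the sharp stimulus onset when the cutoff is close to the signal
  bandwidth; the amplitude-recovery tests therefore use a cutoff well
  above the twitch bandwidth.
* **Pt.** Maximum of the filtered torque within 500 ms after the
  stimulus minus the mean of the 50 ms pre-stimulus baseline (both
  configurable). Baseline subtraction makes Pt invariant to constant
  offsets.
* **Dm/Td/Tc.** The displacement is baseline-subtracted the same way.
  Dm is the first local maximum after the stimulus with prominence above
  `max(0.05 mm noise floor, 5 % of the global maximum)`, earliest wins;
  the global maximum is the fallback. Td/Tc come from the first upward
  crossings of 0.10·Dm and 0.90·Dm before the peak, linearly
  interpolated between samples (integer-sample resolution would add
  ±1 ms quantization at 1 kHz). Dm below 0.1 mm flags the twitch as
  no-displacement (all three values NaN), mirroring a sensor that
  detects nothing.

## Statistical conventions

* **Hedges' g (paired).** Standardized by the *average* of the two SDs,
  not the SD of differences — this is what reproduces the published
  baseline effect sizes (e.g. g = 0.01 for Pt from its summary
  statistics, where difference-SD standardization gives ≈ 0.13) — with
  small-sample correction J = 1 − 3/(4(n−1)−1). The CI is the normal
  approximation g ± 1.96·√(1/n + g²/2n); the printed CIs in the source
  tables are internally inconsistent (e.g. "0.01 (−0.03–−0.04)"), so the
  package reports a self-consistent interval instead of matching them.
* **ICC(A,1).** Mean-squares form of the two-way, absolute-agreement,
  single-rating coefficient with the McGraw–Wong F/Satterthwaite CI;
  verified identical to pingouin's implementation, which the test suite
  keeps as an independent cross-check.
* **SEM/MDC.** SEM = SD·√(1−ICC) with SD pooled over both baseline
  columns; MDC = SEM·1.96·√2; percentages relative to the pooled grand
  mean. MDC/SEM = 1.96·√2 exactly, by construction.
* **Tukey screening.** Fences at Q1 − 3·IQR and Q3 + 3·IQR with
  linear-interpolation quartiles (numpy default). A zero IQR collapses
  the fences, so constant data is never flagged.
* **Missing values.** Interior gaps (and runs) are replaced by the mean
  of the nearest preceding and following observations of the same
  subject; a gap at either end of a series is unresolvable and raises.
* **RM-ANOVA.** Within-subject F from the subject×time decomposition;
  Greenhouse–Geisser epsilon (doubly-centered covariance form) applied
  unconditionally to both dfs and the p-value, matching the fractional
  dfs convention of the source tables; partial η² = SS_time/(SS_time +
  SS_error). With two levels the test reduces exactly to the paired
  t-test (F = t², ε = 1). Because the GG epsilon estimate is biased
  below 1 in small samples, the corrected test is *conservative* when
  sphericity actually holds (measured null rejection ≈ 0.03 at nominal
  0.05 for 16×8); `AnovaResult.p_uncorrected` exposes the
  sphericity-assuming p for calibration work.
* **Bonferroni post hocs.** Each post-baseline timepoint vs baseline;
  p_adj = min(1, p·m) with m = number of post-baseline comparisons for
  that parameter (configurable).
* **Classification.** Strict exceedance of the MDC ("exceeds" means >,
  so a change exactly equal to the MDC is *unchanged*). The same
  increase→potentiated / decrease→fatigued rule applies to every
  parameter, including Td and Tc whose physiological potentiation
  response is a *decrease* — this uniform rule is applied deliberately
  (it is why timing parameters show near-zero potentiation sensitivity);
  no direction-remapping is applied by default.
* **Diagnostic metrics.** Ratios with empty denominators are NaN
  (undefined), never silently zero. DE is computed as overall accuracy
  (tp+tn)/total, which equals the prevalence-weighted Sn/Sp form whenever
  both are defined and gracefully reduces to Sn at prevalence 1.
  Proportion CIs are exact Clopper–Pearson (Beta-quantile form); the
  Youden CI combines the Sn and Sp interval endpoints (a conservative
  convenience, not an exact interval).
* **AUROC.** Rank-based (Mann–Whitney) with ties counted ½. Scores are
  percent changes from baseline, oriented per condition: for fatigue the
  negated change, so "more decreased" ranks higher. The published AUROC
  column is internally inconsistent with its own Sn/Sp rows (some entries
  appear orientation-flipped); the package documents its orientation and
  does not chase those values.

## Problem sizes and runtime

Default analyses run a 16-subject, 18-timepoint cohort at 1 kHz
(~1 s to simulate and extract). The null-calibration study uses 2,000
replicates of a 16×8 matrix; the reliability-vs-noise and
coupling-sweep studies use 3 levels at a fixed seed. These sizes give
Monte Carlo error comfortably below the assertion tolerances while
keeping the whole suite fast.

## Known limitations

* The generator's timing parameters carry no trajectory, so diagnostic
  accuracy of Td/Tc/Vcnorm in simulations reflects only the
  classification machinery, not a physiological timing response.
* The Hedges CI and Youden CI are approximations (see above).
* A schedule is treated as `Pre*`, `Set<k>`, `Post<minutes>` labels; the
  published protocol's "23 measurements" power-analysis count does not
  match its own described schedule, so the schedule is configurable and
  the 18-twitch default is an interpretation.
* Real-data ingestion expects the documented CSV layout (one file per
  subject × timepoint plus a manifest); proprietary acquisition formats
  are out of scope.
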