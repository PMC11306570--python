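# Methods

This note documents the models and procedures implemented in
`contagionkit`, the defaults chosen where the underlying study design
left them open, and what the synthetic-data studies do and do not
demonstrate about real recordings.

## Study design emulated by the generator

A session is 8 blocks of 8 trials. Four blocks carry a fixation cross
between the stimulus eyes (CROSS) and four do not (NO-CROSS); within
a gaze condition the blocks cycle through the four
(emotion ∈ {happy, sad}) × (stimulus pupil ∈ {large, small}) cells, so
each condition contributes 16 large- and 16 small-pupil trials.
Stimuli last 6 s, preceded by a 1 s inter-stimulus fixation (which
doubles as the pupil/EDA baseline window) and each block by a 10 s
fixation. Gaze and pupil are sampled at 120 Hz, skin conductance at
128 Hz, and heartbeat intervals beat-by-beat (analyzed on a 2 Hz
grid). All analysis windows are 0–3 s post stimulus onset.

The cohort is 66 participants aged 6–18 years (age ~ N(129.9, 38.5²)
months, truncated). Trait (AQ) z-scores come from a two-component
mixture — typical N(−0.45, 1.2²) and an oversampled high-trait
component N(1.8, 1.5²) carrying the diagnosis flag (one third of the
cohort) — giving an overall mean ≈ 0.3, SD ≈ 1.7 and a realized range
of roughly −3 to +4.5. Raw questionnaire totals are back-computed
from per-version norm tables (child/adolescent/adult) purely so the
on-disk participant table looks like real data; analysis uses the
z-score.

## Embedded effects

Event-locked effects appear only on large-pupil trials, and (for
pupil and heart rate) only in the CROSS condition:

- **Pupil**: a dilation bump confined to the analysis window with
  raised-cosine onset/offset (support 0.5–2.5 s post onset). Its
  amplitude is normalized so the *discrete mean over the window
  samples* equals the nominal effect: `pupil_contagion_mm`
  (default 0.04 mm) scaled by `1 + β·z` where z is the participant's
  trait z-score. β is solved once by root finding on a pilot
  simulation of 10,000 participants so the cohort Spearman correlation
  between z and the pupil differential score equals
  `aq_contagion_rho` (default 0.28); with the default trial noise this
  gives β ≈ 0.40. The interior support margin keeps the zero-phase
  low-pass transients inside the window, which is why the noise-free
  round trip recovers the amplitude to ~3·10⁻⁷.
- **Heart rate**: `hr_contagion_bpm` (default 2.0 bpm) added to the
  instantaneous rate for every beat whose end time falls within a
  1.2 s pad around the analysis window. The pad (≈ one beat of
  anticipatory lead/persistence) guarantees that every 2 Hz grid
  sample inside the window interpolates between beats that both carry
  the shifted rate, making the injected effect exactly recoverable.
- **Skin conductance**: `scr_contagion_us` defaults to 0 — the study
  condition this package models found no electrodermal contagion —
  but can be set to any amplitude for round-trip testing.

Trial-to-trial response variability (pupil 0.25 mm, HR 4 bpm,
SCR 0.2 µS) is applied as an amplitude perturbation of the same
event-locked shapes on *every* trial, so differential scores inherit
a well-defined noise level shared between the stream generators and
the fast trial-measure generator used for seed sweeps.

## Noise and artefact model

- Pupil: participant baseline ~ N(4.0, 0.4) mm; tonic drift as three
  slow sinusoids (41/67/109 s periods, 0.1 mm scale); band-limited
  sensor noise (3-sample boxcar-smoothed Gaussian, SD 0.05 mm);
  binocular blinks at 1 Hz with 5–30-sample gaps and ±0.2–0.5 mm edge
  spikes; isolated tracker spikes at 0.1 Hz; 3.2% of trials dropped
  entirely. The blink rate is deliberately high to reproduce the
  ~15–20% missing-sample fractions typical of child eye-tracking.
- Gaze: a logistic model for the per-participant probability of
  looking inside the eye AOI — condition median (0.747 CROSS, 0.512
  NO-CROSS) plus an age gradient (0.5 per age SD on the logit scale,
  yielding an age–gaze Spearman around 0.6) plus a participant
  intercept (SD 0.65). Samples are drawn from precomputed point pools
  inside/outside the AOI; 4.5% of samples are missing.
- EDA: tonic level 5 µS with slow sinusoidal drift; SCRs are Bateman
  double-exponentials (rise τ = 0.75 s, decay τ = 2 s, unit-peak
  normalized, ~1.2 s peak latency); spontaneous SCRs at 0.03 Hz;
  movement artefacts (Gaussian transients of ~2–4 µS) on 10% of
  trials, which is what the 2.5 SD exclusion rule is meant to catch.
- RR: participant resting interval ~ N(750, 80) ms; AR(1)
  beat-to-beat variability (SD 25 ms); ectopic beats (single intervals
  deviating 25–45% from their neighbour) and occasional out-of-range
  values, both annotated with ground truth for recovery tests.

What the generator does **not** emulate: fixation/saccade dynamics
(gaze samples are exchangeable within a trial), eye-tracker-specific
noise spectra, pupil foreshortening, emotion (happy/sad) effects on
arousal, luminance-driven pupil responses, or respiratory sinus
arrhythmia structure beyond AR(1). Passing the simulation studies
therefore demonstrates correctness of the *pipeline* under the stated
statistical structure, not robustness to every artefact of real
hardware.

## Preprocessing decisions

- **Dilation speed** is the two-sided maximum of neighbour slopes.
  A consequence pinned down in the tests: a single-sample spike
  contaminates the slopes of both adjacent samples, so the MAD rule
  removes the spike *and* its two neighbours.
- **MAD threshold** = median + 4·MAD with the raw (unscaled) MAD, as
  an upper bound only (speeds are non-negative). A guard handles the
  degenerate case of near-noiseless traces, where median and MAD
  collapse to zero and the literal rule would delete any smooth
  physiological response: removal additionally requires the speed to
  exceed `mad_speed_floor` (default 1.0 mm/s). Artifacts at 120 Hz
  produce speeds of tens of mm/s, far above the floor; physiological
  dilation stays below it. On pure Gaussian noise the rule removes
  ~1.5–2% of samples — an intrinsic property of thresholding a
  max-of-half-normals statistic at median + 4·MAD.
- **Zero-lag filtering** is forward–backward application of the
  stated design order (4th-order pupil low-pass, so an effectively
  8th-order magnitude response). The EDA high-pass is also applied
  forward–backward for phase consistency (configurable).
- **Phasic attenuation**: a 0.05 Hz first-order high-pass necessarily
  attenuates SCR-timescale responses. For the default Bateman kernel
  the chain's net amplitude gain is ≈ 0.87 (measured and locked in a
  regression test against the chain's frequency response). SCR
  amplitudes are therefore systematically conservative; since the
  same gain applies to both large- and small-pupil trials it cancels
  in differential scores.
- **Trial validity**: pupil trials need ≥ 50% cleaned-sample support
  in the analysis window and a non-empty baseline; HR grid samples
  bridged across beat gaps > 3 s are distrusted; SCR outlier SD is
  computed per participant with both conditions pooled (a flag
  switches to per-condition).
- **HR conversion** uses 60000/NN(ms); a strict-replication flag
  reproduces the printed constant 6000 for comparison runs.

## Inference decisions

- Wilcoxon: zeros discarded (Pratt's method by flag), ties mid-ranked,
  W = min(W⁺, W⁻). Exact p for n ≤ 25 via dynamic programming over
  doubled ranks — identical to full 2ⁿ enumeration, verified against
  an explicit enumeration oracle — otherwise normal approximation with
  tie correction and continuity correction. Effect size r = Z/√n,
  signed by the direction of the median difference.
- Semi-partial Spearman: every column rank-transformed; covariates
  (age, amount of gaze in the matching condition) removed from the
  trait side by least squares on ranks; residuals correlated with the
  outcome ranks. p from the t approximation with df = n − 2 − k;
  CI via Fisher z with SE = 1.03/√(n−3).
- No multiple-testing correction is applied across the six contagion
  tests; interpret families of p-values accordingly.

## Simulation studies

- **Type-I calibration** (400 seeds, n = 66, all effects zero): each
  of the six contagion Wilcoxon tests must reject at a rate inside the
  95% binomial interval around 0.05. This study draws per-trial
  measures directly from the generator's statistical model rather than
  synthesizing 400 × 66 full stream sets; the stream chains are
  deterministic transformations whose correctness the known-truth
  tests establish separately, and the calibration question concerns
  the inference layer.
- **Recovery study** (100 seeds in the test suite, 30 in the
  acceptance script): full stream simulation and preprocessing of the
  pupil and gaze modalities at n = 66 with default effects. Expected
  behaviour: significant CROSS pupil contagion in ≥ 80% of seeds,
  non-significant NO-CROSS tests in ≥ 90%, and a mean recovered
  semi-partial correlation within ±0.10 of the 0.28 target.

Problem sizes in the acceptance script (one full multimodal cohort,
400 measure-level seeds, 30 stream-level seeds) are the package's
default desk-scale settings; all are configurable.

## Known limitations

- Landmarks are inputs; no face/landmark detection is provided.
- The half-ellipse parametrization (semi-minor = 0.5 × major-axis
  length, 32 arc vertices) is one reasonable reading of "a
  half-ellipse over the forehead" and is configurable.
- SCR amplitudes are max-of-signal, not trough-to-peak scored; no
  deconvolution-based decomposition is attempted.
- The synthetic stimulus images are schematic (disks and ovals); they
  exercise the luminance measurement code, not photograph realism.
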