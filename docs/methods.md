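# Methods

## The prognosis model

`cipredict` operationalises a binomial-logistic prognosis model for the
monosyllabic word recognition score achieved six months after cochlear
implantation, measured in free field at 65 dB SPL (WRS65(CI), percent).
The linear predictor is in raw clinical units — WRSmax in percent, age
at implantation in years, WRS65(HA) in percent, no centering or
scaling — and the logistic link keeps predictions strictly inside
(0, 100):

η = β0 + β1·WRSmax + β2·age + β3·WRS65(HA),  WRS65(CI) = 100·σ(η).

The packaged default coefficients are β = (0.84, 0.012, −0.0094,
0.0059) with standard errors (0.18, 0.0015, 0.0025, 0.0026)
(`data/default_coefficients.json`). Predictions are monotone increasing
in both preoperative scores and decreasing in age; for WRSmax = 0 and
WRS65(HA) = 0 the prediction is driven by the intercept and age alone.
Display rounds to 0.1 %; all comparisons with measured scores use
unrounded values.

**Uncertainty intervals.** No coefficient covariance matrix is
available for the default set, so `prediction_interval` draws the four
coefficients as *independent* normals at their standard errors, pushes
each draw through the model and takes symmetric tail quantiles. This is
an approximation: correlated coefficient errors would typically narrow
the interval (scores and age are correlated in any fitting cohort), and
its coverage against the source fit cannot be verified. Intervals are
reproducible for a fixed seed and degenerate to the point when all SEs
are zero.

**Refitting.** `refit_coefficients` maximises the binomial likelihood
of observed scores treated as Binomial(n_items)/n_items proportions
(default n_items = 20, one Freiburg monosyllabic list, hence 5 %
steps), in the exact raw-unit parameterisation above. The fit is an
IRLS GLM (statsmodels, binomial family with `var_weights = n_items`);
standard errors come from the information matrix at the optimum.
Degenerate designs (a constant predictor, rank deficiency), perfect
separation and non-convergence raise a fit-failure error with
diagnostics rather than returning numbers. Refitting exists for
parameter-recovery experiments, not to produce deployable clinical
coefficient sets.

## Critical differences for speech audiometry

A score from an n-word list moves in 100/n-point steps and carries
binomial measurement noise, so "improved" must mean "more than
measurement noise apart". The engine models two scores as independent
Binomial(n, p) counts sharing one p under the null, estimated by the
pooled MLE (k_a + k_b)/(2n). The exact pmf of the count difference is
obtained by discrete convolution, and the two-sided p-value is the tail
mass at the observed |difference|; the difference is significant iff
p < α (default α = 0.05, two-sided), with boundary ties non-significant
(conservative). The construction is exact and assumption-light; it
implements the critical-difference *concept* used in German-language
speech audiometry and is not a bit-for-bit reproduction of published
look-up tables (whose null construction is not fully specified). Tests
verify the engine against brute-force enumeration of the full joint
outcome space for every attainable pair at n ∈ {10, 20, 40}, plus the
expected monotonicities: a larger difference in the same direction
stays significant, and significance at a given pair of percent scores
is preserved as n grows.

`classify_change` maps a pre/post pair to improved / unchanged /
deteriorated: a significant difference with the corresponding sign, or
unchanged. n_items is configurable (20 by default, 40 for two-list
testing) because the source protocol does not pin the list count.

## Synthetic cohort generator

No per-patient data are published for the cohort the pipeline is
designed around, so the generator emulates its structure. Per-patient
pipeline and defaults (all in `GeneratorConfig` /
`data/default_generator.json`):

* **Age** ~ truncated normal on [25, 86] years, SD 13.9. The parent
  mean is 67.45 so that the *truncated* mean is 65.0 (truncation at 86
  pulls the mean down ~2.4 years).
* **Ipsilateral audiogram**: a severity draw ~ truncated normal on
  [47, 130] dB HL (parent mean 93.0, SD 21) plus a sloping
  high-frequency pattern (−7.5…+7.5 dB offsets, 4 dB within-ear
  scatter), rounded to the audiometric 5-dB step. Thresholds above the
  120 dB HL audiometer limit become NOT_MEASURABLE and enter the 4FPTA
  as 130 dB HL, exactly as the file readers do, so a cohort written to
  CSV and read back reproduces the same 4FPTA values. Calibrated final
  mean 4FPTA ≈ 92 dB HL. The contralateral 4FPTA (mean 54, SD 26,
  range [3, 95]) is descriptive passthrough only.
* **WRSmax**: zero with probability σ(−8.6 + 0.08·4FPTA) — calibrated
  so ~31 % of the cohort measures zero (≈ 39/124), zero is rare below
  80 dB HL (~5 %) and ~42 % above 80 dB HL; otherwise a latent
  probability σ(3.8 − 0.05·4FPTA + ε), ε ~ N(0, 0.8) on the logit
  scale, capturing listener-level variation beyond the audiogram.
  Measured WRSmax is Binomial(20, p)/20·100; calibrated cohort median
  ≈ 23–25 %.
* **WRS65(HA)**: latent aided probability = 0.15 × the WRSmax
  probability (hearing aids transmit only part of the residual
  function at conversational level), measured binomially; patients
  whose measured WRS65(HA) exceeds 50 % are rejection-resampled from
  the WRSmax step onward, mirroring how the inclusion criterion shapes
  a real cohort (a bounded loop; an unsatisfiable configuration raises
  a generation error). Calibrated median WRS65(HA) = 0.
* **CI outcome**: the latent 6-month probability is the model
  prediction evaluated at the *measured* (noisy) preoperative values —
  as in clinical use — and the rehabilitation course is
  s(t) = p_ci·(1 − e^(−t/τ)) with τ lognormal (median 1 month,
  log-SD 0.3): most of the gain inside the first three months, which is
  what makes a 3-month QA check informative. Visits at months
  {1, 2, 3, 6, 12} are sampled Binomial(20, s(t)).
* **Injected QA patterns**: with 2 % probability each, a patient's
  course is replaced by a *flat* trajectory (asymptote 0.3·p_ci) or a
  *fluctuating* one (level 0.4·p_ci with N(0, 0.15) visit-level
  perturbations), emulating the rare unexpectedly-poor outcomes the QA
  workflow exists to catch. Set both rates to zero for clean-model
  experiments.

All randomness flows from the single config seed through one
`numpy` Generator; identical configs give identical cohorts (and
byte-identical CSVs through the CLI).

**What the generator does and does not emulate.** It reproduces the
marginal demographics, the audiogram–speech-score links, the inclusion
criterion and the measurement noise of the study cohort. Its outcomes,
however, are generated *by the prognosis model itself*: apart from
injected patterns there is no outcome heterogeneity beyond binomial
noise and the rehabilitation time constant. Passing validation on such
cohorts therefore demonstrates the pipeline's correctness and the
measurement-noise floor (median absolute errors ≈ 7 points), not the
model's clinical accuracy — real cohorts show larger subgroup errors
because auditory-nerve status, deafness duration and aetiology are not
in the model. In particular the qualitative subgroup ordering (WRSmax=0
validates worse than WRSmax>0) emerges here only through the binomial
variance profile p(1−p) — the zero subgroup sits near p ≈ 0.55 where
noise is maximal — a much smaller effect (~0.5 points) than the
clinically observed gap (23.2 vs 11.5 points); the ordering test uses
20,000 patients per seed so that seed noise sits below that effect
size.

## Validation pipeline

* The 6-month endpoint is the visit nearest month 6 within ±1 month
  (visit jitter); absence raises an explicit missing-endpoint error.
* Error = measured − predicted, classified into within ±10 points /
  short by > 10 / above by > 10 (an exhaustive, mutually exclusive
  partition).
* "MAE" throughout is the **median** absolute error
  (`median_absolute_error` in code), robust to the long tail of poor
  performers; computed overall and per WRSmax subgroup.
* Improvement vs WRS65(HA) and the below-WRSmax check use the same
  critical-difference engine and α.
* *Unexpectedly poor*: prediction exceeds the measurement by more than
  20 points. Only such cases, with ≥ 3 visits including month 12, enter
  the trajectory cascade: achieved-by-12-months (12-month score within
  20 points of the prediction; evaluated against the model's 6-month
  prediction, the model's defined horizon) → fluctuating (residual SD
  around an isotonic fit > 10 points) → delayed increase (slope over
  the last two visits ≥ 2 points/month) → flat. The two numeric
  thresholds are configurable; the defaults separate the injected
  generator patterns cleanly and follow the qualitative clinical
  descriptions (a 5-point visit-to-visit step is one word on a 20-word
  list, so residual SD > 10 means swings of several words).
* The 3-month QA check orders its rules by clinical priority: a score
  significantly below WRSmax (the lower estimator) flags
  `below_lower_bound` first; otherwise a score above the prediction is
  `above_prediction`; everything else is `within_corridor`.

## Numerical and design notes

* Attainability is enforced everywhere: a percent score must be a
  k/n_items multiple (tolerance 1e-6) or the operation raises a
  validation error — this catches unit mistakes (proportions vs
  percent) early.
* The critical-difference tail mass is cached per (k_a, k_b, n), making
  large-cohort evaluation cheap.
* Generator calibration constants were fixed once by a coarse
  simulation search against the published cohort summaries and then
  frozen; they are ordinary config values, not fitting targets.
* Experiment sizes in the shipped tests (10 × 5000 refits, one
  10,000-patient calibration cohort, 20 000-patient ordering cohorts)
  were chosen so Monte-Carlo error is comfortably below each effect
  being tested.

## Known limitations

* The coefficient-independence approximation in the Monte-Carlo
  interval (above).
* The WRSmax–WRS65(HA) link (a single attenuation factor) is a
  modelling choice; the joint distribution of the two scores is not
  published beyond qualitative patterns.
* The generator models neither aetiology, deafness duration,
  contralateral-CI status nor device type; these are passthrough
  metadata at most.
* The pipeline flags cases; it does not attribute causes (device
  faults, therapy adherence) — that is an interdisciplinary clinical
  decision.
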