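# Methods

## Model and fitting

The package models cross-sectional age as a power law in serum AMH,
age = β0·AMH^(−β1), and fits it by ordinary least squares after the log–log
linearization ln(age) = ln β0 − β1·ln(AMH). The linearization makes ln β0 the
fitted intercept, admits a closed-form solution (no convergence concerns), and
is the formulation under which the published coefficient pairs reproduce the
published menopause predictions. A nonlinear least-squares fit on the natural
scale is deliberately out of scope: it answers a different estimation question
and would not correspond to the reported coefficients.

Two modelling conventions deserve emphasis:

- **Regression direction.** The model regresses age on AMH, as written, even
  though biologically AMH is the response given age. Fidelity to the printed
  formula is the point: predictions are read off the fitted curve at an AMH
  value. The consequence — attenuation when noise sits on AMH — is quantified
  below under the generator's modes.
- **Menopause as a threshold crossing.** Menopause is operationalized as the
  age at which the modelled curve crosses an AMH cutoff, default 0.2 ng/mL
  (configurable). The predicted age is simply β0·cutoff^(−β1). Ages are
  rounded to 1 d.p. only at the reporting layer.

Fit diagnostics (r², residual SD) are reported on the log–log scale, where
the least-squares criterion lives. A fit needs ≥ 3 points with ≥ 3 distinct
AMH values; fewer distinct values is a degenerate design and a hard error.
AMH values ≤ 0 are likewise a hard error: the caller must either exclude them
or opt into an explicit limit-of-quantification policy
(`apply_loq_policy`, which substitutes LOQ/2 below a stated limit) — never a
silent offset.

The inverse curve AMH(age) = (age/β0)^(−1/β1) supplies decline curves; the
decline ("de-acceleration") rate is the analytic derivative d(AMH)/d(age) =
−AMH(age)/(β1·age). Because the ordering of two groups' |rates| can change
along the age axis, `compare_decline` reports a per-age verdict and summary
win fractions rather than asserting a single global winner.

## Uncertainty

`bootstrap_menopause_ci` uses nonparametric case resampling: subjects are
resampled with replacement, each replicate is refitted with the same
closed-form OLS (vectorized over replicates), and the percentile interval of
the replicate menopause ages is reported (default n_boot = 1000, level 0.95,
explicit seed). Replicates with fewer than 3 distinct AMH values are redrawn,
capped at 10·n_boot draws. In tiny or heavily skewed samples a raw percentile
endpoint can land on the far side of the full-sample point estimate; the
interval is widened to bracket the point estimate so the reported triple is
always coherent. This is the simplest defensible interval for a two-parameter
fit; BCa or studentized intervals were judged unnecessary at n = 500.

## Synthetic cohorts

The generator emulates two clinic cohorts of n = 500, ages 30–35 years:
a PCOS group (BMI truncated-normal in 24–31 kg/m², centred 27.5; generative
coefficients β0 = 41.41, β1 = 0.17) and a eumenorrheic group (BMI 22–28,
centred 25.0; β0 = 35.49, β1 = 0.15). One master seed expands into fixed
per-purpose streams (ages, AMH noise, BMI, assay, FSH, cycle length), so
adding a stream never perturbs the others, and identical parameters give
bit-identical cohorts down to the CSV bytes.

**Two modes, on purpose.** The regression direction (age on AMH) and the
biological generative direction (AMH given age) differ, so the generator
offers both error structures:

- `amh_noise` (default): age is drawn from the cohort age window and
  ln(AMH) = (ln β0 − ln age)/β1 + ε, ε ~ N(0, σ²), floored at 0.01 ng/mL.
  This emulates a bounded-age cross-sectional cohort. Because the noise sits
  on the *regressor*, refitting age-on-AMH on such data suffers classical
  errors-in-variables attenuation — with the default σ the fitted β1 shrinks
  toward 0. That is a property of the study design being emulated, not a bug;
  parameter-recovery claims are therefore never made in this mode.
- `age_noise`: ln(AMH) is drawn uniformly over a stated window (default
  0.2–10 ng/mL) and ln(age) = ln β0 − β1·ln(AMH) + ε. This makes the OLS
  error assumption true, so recovery is unbiased; all recovery and
  bootstrap-coverage simulations use this mode. Ages are then unbounded.

**Age distribution and calibration.** In `amh_noise` mode ages default to a
truncated normal on [30, 35] (SD 1.5 y) whose location is solved so the
truncated mean equals the cohort's reported mean age (33.4 y PCOS, 34.3 y
eumenorrheic). A uniform draw is available as an option, but it cannot serve
as the calibrated default: its mean age is 32.5 y, and with the eumenorrheic
coefficients the curve's average AMH over a uniform 30–35 age draw is already
1.89 ng/mL — above the 1.64 ng/mL target — while multiplicative lognormal
noise can only inflate the mean. Under the truncated-normal default the
log-scale biological-scatter SDs were set once by numerical integration so
that E[AMH] = E[(β0/age)^(1/β1)]·exp(σ²/2) matches the reported group means
(4.95 and 1.64 ng/mL): σ = 0.79 (PCOS) and 0.72 (eumenorrheic). These imply a
natural-scale AMH CV near 90%, in line with the wide dispersion of AMH in
reproductive-age women.

**Assay noise.** ELISA measurement error is modelled separately from
biological scatter as a single multiplicative lognormal factor whose CV
combines the intra- and inter-assay CVs (5.3%, 8.7%) in quadrature
(√(0.053² + 0.087²) ≈ 10.2%); no replicate structure is modelled. The factor
is mean-preserving (log-location −σ²/2, σ² = ln(1+cv²)), so assay noise does
not bias the cohort mean. Measurements below the assay sensitivity
(0.7 pmol/L = 0.098 ng/mL at the standard 7.14 pmol/L-per-ng/mL conversion)
are reported at the sensitivity floor and flagged in the cohort metadata.

**What passing tests do not show.** The generator reproduces the two cohorts'
first moments (mean age, BMI, AMH) and the assumed power-law age–AMH
structure. It does not reproduce real AMH distributions' heavy right tail
beyond lognormality, age–BMI correlation, longitudinal within-woman
trajectories, or follicle counts; recovery results in `age_noise` mode say
nothing about the bias of age-on-AMH fits on real (amh-noise-like) cohorts.

## Eligibility and data handling

All inclusion windows are closed intervals (boundaries included): the PCOS
screen is age 30–35 y, BMI 24–31 kg/m², FSH 1–10 IU/L, oligomenorrhea or
amenorrhea; the eumenorrheic screen is age 30–35 y, BMI 22–28 kg/m², regular
cycles of 26–35 days. Menstrual status is consumed as a pre-coded flag, never
inferred from bleeding records. Exclusion logs record the first violated
criterion in a fixed evaluation order (age, BMI, FSH, cycle, status) for
deterministic reports. Cohort CSVs are comma-separated UTF-8 with a mandatory
header and decimal points; floats are written at shortest round-trip
precision so write→read is lossless. The canonical analysis unit is ng/mL;
pmol/L values convert at 7.14 pmol/L per ng/mL.

## Reporting conventions

Published tables label the 41.41/35.49 column as a log-coefficient, yet the
published menopause ages are reproduced only when those numbers are β0 itself
(35.49·0.2^(−0.15) = 45.2). The package follows the numbers: coefficient
pairs are consumed as (β0, β1), and reports print both β0 and ln β0 under
unambiguous headers. Direct evaluation with the PCOS pair gives 54.4 years
where published texts print 54.5 or 54.7; the ≤ 0.3-year residual is
consistent with the coefficients having been rounded to 2 d.p. before
publication, and the computed value is reported as computed. Coefficients are
rendered at 2 d.p. and ages at 1 d.p. in tables only.

## Pipeline determinism and problem sizes

A pipeline run is fully determined by its config: generator seeds and the
bootstrap seed live in the config, whose canonicalized YAML is hashed
(SHA-256) into the run manifest alongside stage counts. Re-running a config
byte-identically reproduces every output file.

Simulation studies in the test suite use the study's own scale: n = 500
subjects per cohort, 200 simulated cohorts for parameter recovery and
bootstrap coverage (n_boot = 500 replicates each, vectorized), 50 seeds for
mean-AMH calibration checks. The recovery simulations use σ_log = 0.02 in
`age_noise` mode, a small perturbation chosen so bias, not noise, would
dominate any failure.

## Known limitations

- A single power law cannot represent a biphasic follicular-atresia pattern
  (e.g. an accelerating loss after the late 30s); no piecewise or multiphasic
  model is provided.
- Extrapolation: cohorts span ages 30–35, while menopause predictions
  evaluate the curve far outside that window (45–55 y). The model is a
  deliberate extrapolation device; the bootstrap interval reflects sampling
  error only, not extrapolation bias.
- No survival/time-to-event formulation, no FSH/inhibin/AFC modelling, and no
  per-subject menopause prediction — the prediction is a group-level curve
  crossing.
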