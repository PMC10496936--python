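# amhage

Power-law modelling of age over serum anti-Müllerian hormone (AMH) to predict
age at menopause, for biostatisticians and reproductive-endocrinology
researchers comparing PCOS and eumenorrheic cohorts.

Serum AMH, secreted by granulosa cells of preantral and small antral
follicles, tracks the remaining ovarian follicle pool and declines with age.
`amhage` fits the cross-sectional model

    age = β0 · AMH^(−β1)        ⇔        ln(age) = ln β0 − β1 · ln(AMH)

per study group by ordinary least squares on the log–log scale, and
operationalizes menopause as the age at which the modelled AMH curve crosses a
cutoff (default 0.2 ng/mL), i.e. the model evaluated at the cutoff:
β0 · 0.2^(−β1). It also computes the decline rate d(AMH)/d(age) =
−AMH(age)/(β1·age) along the inverse curve, compares two groups' rates age by
age, and attaches a case-resampling bootstrap percentile interval to the
predicted menopause age. A calibrated synthetic-cohort generator (two groups
of n = 500, ages 30–35, with ELISA assay-noise emulation) makes every pipeline
stage testable without clinical data.

## Worked example

Evaluate the model at the cutoff for known coefficients:

```
$ amhage predict-menopause --beta0 35.49 --beta1 0.15
predicted_menopause_age=45.2
```

Run the full two-group pipeline on simulated cohorts (`age_noise` mode, the
generator mode whose error structure matches the regression's assumption) with
a bootstrap interval, from a YAML config:

```yaml
# config.yaml
groups:
  - {group: pcos,         gen_params: {seed: 1, mode: age_noise, sigma_log: 0.05}}
  - {group: eumenorrheic, gen_params: {seed: 2, mode: age_noise, sigma_log: 0.05}}
cutoff: 0.2
bootstrap: {enabled: true, n_boot: 1000, level: 0.95, seed: 1}
```

```
$ amhage run --config config.yaml --out out/
       group log_beta0 beta0 beta1 cutoff predicted_menopause_age ci_low ci_high
        pcos      3.72 41.43  0.17    0.2                    54.7   54.2    55.2
eumenorrheic      3.57 35.50  0.15    0.2                    45.2   44.8    45.6
```

Each row is one group's fit: `beta0` (years) and `beta1` (dimensionless) are
the power-law coefficients recovered from the simulated cohort — here within
rounding of the generative truth (41.41/0.17 and 35.49/0.15) —
`predicted_menopause_age` is β0·cutoff^(−β1) in years, and `ci_low`/`ci_high`
bound it by a 95% case-resampling bootstrap. The PCOS group's flatter decline
(smaller |β1| effect via higher AMH at every age) yields menopause ~9.5 years
later than the eumenorrheic group. `out/` additionally receives per-group
decline-curve CSVs (age, amh, rate), a per-age rate comparison, filtered
cohort CSVs with exclusion logs, and a run manifest with the config hash.

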