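# artcov

Day-level antiretroviral-therapy (ART) **prescription coverage** from
pharmacy records, and a mixed-effects evaluation of a weekly SMS
adherence-support program at a government HIV clinic.

Pharmacy refill data give a conceptual ceiling on pill-taking adherence: a
day is *covered* when the patient holds a valid prescription supplying
their full regimen for that day. `artcov` turns raw prescribing records
into per-patient daily coverage series under clinic rules (a 30-day
carryover cap at refills of an unchanged regimen, removal of re-recorded
balances of 6-month scripts, right-censoring at transfer-out), builds an
intention-to-treat cohort of exposed (sent weekly SMS), unexposed (no phone
number on file) and unknown (chart unavailable) patients, and estimates the
program effect as a group × period interaction in a patient-level
random-intercept logistic model. Because the clinic data underlying the
original evaluation were never deposited, a first-class synthetic-clinic
generator reproduces the cohort's statistical structure for testing,
calibration and power/recovery studies.

It is aimed at biostatisticians and implementation-science researchers
evaluating mHealth adherence programs from routine pharmacy data.

## The model

With one row per patient-day (each patient weighted by their observation
length), the outcome `covered ∈ {0,1}` follows

```
logit P(covered_ij = 1) = β₀ + x_ij'β
                        + γ_E·Exposed_i + γ_U·Unknown_i           (group)
                        + γ_T·During_j                            (period)
                        + δ_E·Exposed_i·During_j
                        + δ_U·Unknown_i·During_j                  (program effect)
                        + u_i,      u_i ~ N(0, σ_u²)
```

with reference levels group = Unexposed, period = pre-program, so each
reported contrast is a single coefficient: `exp(γ)` are pre-program
coverage odds ratios and `exp(δ)` are the program effects. Candidate
covariates `x` (age, gender, prior ART duration, prescription length,
regimen line, fixed-dose combination, a missing-data indicator) are pruned
by stepwise backward elimination at Wald *P* = 0.25; group, period and
their interaction are retained a priori. The fit is exact maximum
likelihood via adaptive Gauss–Hermite quadrature (`artcov.mixedlogit`,
cross-checked against `lme4::glmer` and, in the σ_u → 0 limit, ordinary
logistic regression).

An exposure odds ratio is translated to an absolute effect by odds
division: at observed mean coverage `p`, the hypothetical no-exposure
coverage is `p' = (odds(p)/OR) / (1 + odds(p)/OR)` and the effect is
`(p − p') × 365.25` days of covered treatment per year.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
clinic and write their tables under `results/`:

```bash
python analysis/01_simulate_clinic.py          # 600-patient clinic
python analysis/02_descriptives.py             # exclusions, baseline table, McNemar
python analysis/03_fit_models.py               # program-effect models
python analysis/04_parameter_recovery.py       # estimator calibration study
```

On the default 600-patient clinic (seed 20130909), `03_fit_models.py`
prints:

```
[full] n=596 patients, 200275 patient-days; eliminated: first_line, missing_any, age_years, female, art_duration_30d
  program effect (Exposed vs Unexposed): OR 1.288 (95% CI 1.063-1.559), p = 0.0096
  Exposed during-program coverage 96.6% -> absolute effect 3.4 days/year
```

Read: after elimination, exposed patients' daily odds of holding a valid
prescription rose 1.29-fold from the pre-program to the program period
relative to unexposed patients; for a patient at the exposed group's
average during-program coverage (96.6%) that is ≈3.4 extra covered days
per year. (The generator's true effect is OR 1.25; single synthetic
cohorts scatter around it — `04_parameter_recovery.py` quantifies exactly
how much: mean estimate 1.288, RMSE 0.111 and 97% CI coverage over 30
replicates at n = 300.)

The same pipeline is available as a CLI:

```bash
artcov simulate --out clinic/ --n 600 --seed 7
artcov report --data clinic/ --out out/        # tables + manifest.json
```

## Layout

```
src/artcov/        io, coverage, cohort, mixedlogit, glmm, simulate, pipeline, cli
analysis/          numbered narrative drivers (simulate → descriptives → models → recovery)
tests/             unit, property and acceptance tests
docs/methods.md    modeling assumptions, generator design, numerical choices
```
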