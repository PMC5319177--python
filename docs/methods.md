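# Methods

## Prescription coverage

The outcome is a per-day indicator that the patient held a valid
prescription for their full ART regimen. Coverage is computed from a
single scalar balance of days of supply:

* A `d`-day prescription issued on day `t` covers `[t, t+d−1]`; all
  intervals are closed and counted inclusively.
* At each issue, if the agent set equals the previous prescription's agent
  set, the remaining balance is credited up to a cap (default 30 days,
  clinic policy) before the new duration is added; a regimen change
  forfeits the balance. The cap applies to the carried-over remainder
  only, not to the sum — this is the reading consistent with the policy's
  worked example (15 remaining + 30 new = 45 available), and the
  alternative (capping the sum) would contradict it.
* Between issues the balance decays one day per calendar day and never
  goes negative. A day is covered iff the balance is positive.
* The fixed-dose-combination flag is packaging metadata: co-formulation
  does not change the agent set and therefore never forfeits carryover.

Duplicate rule: a record whose agent set matches an earlier kept record
and whose interval is fully contained in it is treated as a re-recorded
balance (e.g. a 3-month entry three months into a 6-month prescription)
and dropped before any balance arithmetic. Containment-with-identical-
agents is a formalization choice; only one canonical example of the
practice exists, and containment is the weakest rule that removes it
without touching genuine early refills.

A deliberately naive day-by-day pill-inventory simulation serves as the
oracle in tests; the engine's interval arithmetic must agree with it
exactly on randomized histories.

**A note on monotonicity.** Adding a prescription does *not* always
(weakly) increase coverage: a balance `b > cap` at a short same-agent
refill of duration `d` is truncated to `cap + d`, which is smaller than
`b` whenever `b − cap > d`. This is an intrinsic consequence of the
carryover cap, not an implementation artifact. The restricted form that
does hold — appending a same-agent refill of maximal duration never
uncovers a day — is property-tested.

## Observation windows and cohort

Observation begins at the later of the observation-period start
(2013-07-01) and the earlier of (a) the day after the first recorded
prescription ends and (b) the day of the second recorded prescription (so
patients contribute only after care is plausibly established); it ends at
transfer-out or the end of pharmacy data (2014-06-26). Patients are
included if adult (≥18 years at the data-availability start, 2012-11-04,
the reference date for age and treatment duration), enrolled on or before
the observation start, holding at least one (deduplicated) prescription
issued inside the observation period, with phone availability assessed
before the observation period, and with a non-empty window. Exclusions are
applied in that fixed order and each screened patient is counted once
under the first criterion it fails, which makes the tally unique for
patients failing several.

Groups are intention-to-treat functions of the phone fields only:
*Exposed* (number captured before the observation period — messages were
sent), *Unexposed* (chart reviewed, no number), *Unknown* (chart
unavailable). Opt-outs and delivery failures are recorded but never move a
patient between groups.

The program-period boundary day (2013-09-09, the launch day) is labeled
during-program; pre-program is 2013-07-01 through 2013-09-08 (70 days).
The launch-day side of the boundary is a convention; nothing downstream is
sensitive to one day.

Missing non-prescription covariates (age, gender may be absent in the
records) are mean-substituted from the included cohort, with a
patient-level indicator offered to the model as a candidate covariate.
Mean substitution preserves the cohort mean by construction; the binary
gender covariate may therefore take a fractional imputed value.

## The model

One row per patient per in-window day: daily resolution keeps time-varying
covariates (treatment duration, active prescription length and regimen
flags, carried forward across uncovered gaps) aligned with the outcome,
and weighting patients by observation length falls out automatically.
The model is a logistic regression with a patient random intercept;
reference levels (group = Unexposed, period = pre-program) make every
reported contrast a single coefficient. Wald intervals and p-values are
used throughout, including during elimination.

Backward elimination refits the model, removing the single candidate with
the largest Wald p-value above 0.25, until none remains; the group,
period and interaction terms are never candidates. Candidates without
variation in the data at hand (e.g. no fixed-dose user in a small subset)
are structurally unestimable and dropped up front with a log entry, as
are a-priori contrast columns for a group absent from a subset.

The absolute translation divides the coverage odds at the exposed group's
observed during-program mean by the interaction OR and scales the coverage
difference by 365.25 days (both 365 and 365.25 reproduce the published
headline figure to one decimal; 365.25 is used).

### Fitting

No installed Python package offers maximum-likelihood frequentist
inference for a binary-outcome mixed model, so `artcov.mixedlogit`
implements it directly:

* identical covariate rows within a patient are collapsed to binomial
  cells (the likelihood is unchanged), which makes patient × period
  designs nearly free to fit;
* the per-patient integral over the random intercept uses adaptive
  Gauss–Hermite quadrature (default 9 nodes) centered and scaled at the
  integrand's Newton mode — necessary because patients contribute
  hundreds of days and the integrand is far narrower than the prior;
* columns are internally standardized for optimizer conditioning
  (estimates and covariance are mapped back exactly);
* L-BFGS-B maximizes the likelihood with an analytic score (quadrature
  centering held fixed, exact up to quadrature error); σ_u is optimized
  on its natural scale with a tiny positive floor, so σ_u → 0 degrades
  smoothly to ordinary logistic regression;
* standard errors come from the observed information (numerically
  differentiated score); a non-positive-definite information matrix or
  optimizer failure flags the result as non-converged, which the pipeline
  reports rather than hides.

Tests pin the implementation to three independent references: brute-force
numerical integration of the likelihood (`scipy.integrate.quad`),
statsmodels `Logit` in the σ_u = 0 limit, and `lme4::glmer` (nAGQ = 9),
which agrees to ~4 decimals on coefficients, standard errors, σ_u and the
log-likelihood.

## Synthetic clinic generator

No patient data were released with the evaluation this package
re-implements, so `artcov.simulate` generates clinics with the cohort
structure the analysis assumes. Two modes:

**Behavioral** mode emits patients, prescriptions and program events.
Cohort marginals target the published composition: group mix
78.5/14.0/7.5% (Exposed/Unexposed/Unknown), 70% female, log-normal age
matched to median 37.7 (IQR 32.4–43.9) years and treatment duration to
median 2.4 (1.5–3.3) years, prescription-length mix 13/15.5/12.5/59%
across 1/2/3/6-month scripts (each patient keeps a characteristic
length), 94.6% first-line, 1.6% fixed-dose combination at baseline with a
during-program rollout ramp, 3.4% transfer-out, a 0.5 chance that each
6-month script spawns a re-recorded 90-day balance record, 2% missing
covariates, and rare late enrollments/delayed phone captures to exercise
every exclusion branch. Refill behavior: at each prescription's scheduled
end the patient refills on time with probability
`logistic(base + u_i + group/period effects)`, else after a geometric gap
(mean 9 days); the baseline on-time logit (0.9) was set so realized daily
coverage sits in the mid-90s like the clinic being emulated. The Exposed ×
during-program boost on the on-time logit was calibrated once by bisection
(`calibrate_gap_effect`, seed-averaged large cohorts through the full
pipeline) so the *realized daily-coverage* interaction OR matches
`true_effect_or` within 2%; the calibrated constant (0.3875 for OR 1.25)
is the default and other targets scale it log-linearly. Prescription
length is drawn independently of adherence — a simplification the real
joint distribution surely violates — and the generator's gap-level
intercept SD is not the same quantity as the daily-model σ_u (one missed
refill produces a run of correlated uncovered days, so day-level
heterogeneity is amplified).

**Model-faithful** mode bypasses prescriptions and draws the patient-day
table directly from the analysis model's own equation with known
coefficients (program effect ln 1.25, period ln 0.61, σ_u = 0.8, baseline
logit 3.0, covariate effects at plausible published magnitudes; prior ART
duration has a true zero effect, so elimination should usually remove it,
and slow-moving covariates are held constant within patient × period so
the table is an exact draw from the fitted likelihood). This is the mode
for parameter-recovery claims, where the estimand must equal a known
constant by construction: inverting daily-coverage odds into refill-gap
distributions exactly is intractable, so behavioral mode can only be
calibrated, not exact.

Determinism: each patient's random sub-stream derives from
`(seed, patient index)` by counter, so enlarging a cohort never perturbs
existing patients.

What passing tests do and do not show: the generator reproduces the
*structure* the method assumes (grouped binary outcomes with a patient
intercept, censoring, duplicates, carryover). Real pharmacy data add
features it does not model — informative transfer-out, prescription
lengths chosen in response to adherence, mid-stream regimen switches
beyond the rare random ones, seasonal clinic closures — so recovery
results certify the estimator, not the design's robustness to those
violations.

## Problem sizes and numerical choices

Defaults were chosen to keep every routine check desk-scale: analysis
scripts run a 600-patient clinic (a `--n 2255` flag reproduces the
full-scale cohort), recovery studies use 300 patients × 361 days per
replicate with 30–50 replicates, and the oracle equivalence check uses
1,000 random histories. Quadrature uses 9 adaptive nodes for reported
fits (5–7 for calibration scans, where only point estimates matter);
Newton mode-finding iterates to |gradient| < 1e-9 with steps clipped at
±4; the σ_u floor is 1e-6; ties at a prescription issue are processed in
record order. Degenerate inputs fail loudly: a constant outcome, a
singular design, fewer than two groups, or an empty subset each raise a
typed error rather than returning numbers.

## Known limitations

* Dispensing within a prescription is not modeled (a 6-month script
  dispensed as two 3-month pickups counts as prescribed coverage from the
  prescription record, per the data's semantics).
* No per-protocol analysis: opt-out and delivery data are summarized
  descriptively only, because the estimand is intention-to-treat.
* Wald inference everywhere; profile-likelihood or bootstrap intervals are
  out of scope.
* The published real-data coefficients cannot be reproduced (the data were
  never deposited); agreement is demonstrated on worked examples,
  closed-form translations and simulation recovery instead.
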