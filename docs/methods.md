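# Methods

## Scoring engines

Risk models are data, not code: a JSON registry entry holds a name, a
family (`logistic` or `aggregate`), an intercept (logistic only), an
ordered coefficient/point map and per-covariate *coding rules* (numeric
as-is; indicator against a reference level; threshold; age band). The two
generic engines evaluate any spec that validates: logistic specs produce
`LP = β₀ + Σβᵢxᵢ` and `p = expit(LP)`; aggregate specs produce a
non-negative integer point total. Coding conventions for the shipped
Eurolung-family entries: male sex = 1, thoracotomy = 1 (VATS = 0),
extended resection = 1. Scoring is complete-case: a missing or NaN
covariate raises an error naming it; nothing is imputed.

The shipped registry carries the 2016E1 coefficient set as republished in
the validation study's updating table. The 2019E1, Brunelli and aE1
entries could not be verified against a primary document when this package
was assembled; their `provenance` strings flag them as unverified
transcriptions to be replaced from the original tables before clinical
use. ACCI uses the original Charlson weights restricted to the
comorbidities the cohort schema captures (coronary disease, cerebrovascular
disease, COPD, uncomplicated diabetes = 1; renal disease = 2) plus one
point per age decade from 50–59 (1) to ≥80 (4). Since every coefficient
lives in the registry file, a correction is a data edit.

## Spirometry

Percent-of-predicted is `100·measured/predicted`, with predicted normals
from a sex- and age-band-stratified table of linear equations
`litres = const + b_h·height_cm + b_a·age`. Published tables of this form
stop at age 81; for older patients each parameter is regressed linearly on
the age-band midpoint over the three oldest bands (the smallest window
that defines a line robustly; configurable) and extrapolated, and the
result is flagged as extrapolated. Ages below the youngest band raise —
extrapolating toward childhood would cross a growth phase the adult
equations do not model. The shipped parameter table is **synthetic**
(plausible magnitudes, correct structure); digitising a published
reference table is deliberately out of scope, and users substitute their
own table via `load_reference_table(path)`.

ppoFEV1% uses the conventional segment count:
`ppoFEV1% = FEV1% · (19 − s)/19` with s segments removed (lobectomy counts
from the shipped anatomy table: RUL 3, RML 2, RLL 5, LUL 5, LLL 4; default
per-procedure counts segmentectomy 2, lobectomy 4, bilobectomy 7,
pneumonectomy 10). Centres that count subsegments can swap the anatomy
table; the formula itself is the standard convention and the choice is
surfaced rather than hidden.

## Discrimination

AUC is the Mann–Whitney two-sample statistic computed from midranks (ties
count ½), identical to the trapezoidal ROC area. The default 95% CI is
DeLong's structural-components variance with a normal interval clipped to
[0, 1] — deterministic, which matters for byte-reproducible reports. A
stratified percentile bootstrap (`ci_method="bootstrap"`, fixed seed) is
available when the normal approximation is suspect (very small event
counts, AUC near 1).

## Calibration

*Hosmer–Lemeshow.* Cases are sorted by predicted risk and cut into g
near-equal groups at rank boundaries; tied probabilities are never split
(so heavily discretised scores can form fewer than g groups, and the
reported g is the number formed). The statistic is
`Σ (O−E)²/(n_g·p̄·(1−p̄))` over groups with p̄ ∈ (0,1); p comes from χ²
with df = g − 2, the classic convention, kept also for external validation
and documented here because the df convention materially changes p. With
df < 1 the statistic is returned and p marked unavailable. The group count
uses the adaptive rule `g = max[10, min(m/2, (n−m)/2, 2 + 8n²/10⁶)]`
(floored) for 1000 < n ≤ 25000 and g = 10 otherwise; at n = 1085, m = 91
this gives 11. The type-I error of the whole pipeline is verified by
simulation in the test suite: over 1000 seeded replicates of n = 2000 with
the model *refit on each replicate* (the setting in which the g − 2
reference distribution is derived), the rejection rate at α = 0.05 must
fall in [0.03, 0.07]. When fixed, externally given probabilities are
tested instead, the statistic is closer to χ²_g and the g − 2 convention
is anti-conservative — a known property of the test, not a defect of the
implementation.

*Weak calibration.* Slope and intercept come from an unpenalized logistic
fit of outcomes on logit(p) (probabilities clipped to [1e−15, 1−1e−15]
only for the log-likelihood). Slope 1 / intercept 0 is perfect weak
calibration; constant predictions or separation raise. Curve points are
fixed-count risk-decile means (deterministic), not a smoother.

## Threshold metrics

Candidate thresholds are the midpoints of consecutive distinct scores plus
±∞; a case is called positive at score ≥ threshold; the report maximising
the Youden index is returned, ties broken toward the lowest threshold
(favouring sensitivity, the usual screening preference). PPV/NPV are
undefined (NaN) when a margin is empty. The Bayes identity
`PPV = sens·prev / (sens·prev + (1−spec)(1−prev))` is enforced by test on
random confusion tables.

## Updating

All three updaters are unpenalized maximum likelihood (Newton for the 1–2
parameter recalibrations, IRLS for the full revision; gradient tolerance
1e−8, ≤100 iterations). Separation is declared when the solver fails or
any |coefficient| exceeds 15 and is raised as an error: with ~91 events
and sub-1% comorbidity prevalences, covariates with zero events among
carriers are a realistic occurrence, and a silent ±20 coefficient is worse
than a refusal. Full revision therefore generally needs cohorts large
enough that every covariate has events (the test suite uses n = 20000).

`UpdatedModel.alpha` is always the *total* new intercept — the number a
registry file would carry — so method 2 stores `a + b·β₀` rather than the
raw fitted `a`. Serialized updated models are immediately scoreable.
Structural invariants enforced by tests: method 1 changes only the
intercept; method 2 scales all coefficients by one common slope; methods
1–2 preserve the AUC exactly; after any method the mean predicted
probability equals the observed event rate (intercept score equation).
Updating is defined for logistic-family models only; aggregate scores have
no probability scale to recalibrate.

## Synthetic cohort generator

The generator emulates the *marginal* structure of a single-centre
east-Asian resection cohort. Continuous covariates are truncated normals
matched to published medians and IQRs (σ = IQR/1.349): age 60 (52–65) on
[18, 90] (rounded to years), BMI 23.9 (22.0–26.1), ppoFEV1% 76 (68–86) on
[30, 130], FVC% 88.91 (79.87–98.52). Binary prevalences are the published
ones (male 38.99%, CAD 5.44%, CVD 2.12%, CKD 0.46%, arrhythmia 2.12%,
COPD 3.78%, diabetes 11.98%, hypertension 28.76%, smoking 21.66%, alcohol
12.81%, VATS 97.70%, extended resection 1.11%); resection type is
multinomial at 210/863/11/1 of 1085. FEV1% is back-computed from the
sampled ppoFEV1% and the resection's segment count so the spirometry
triplet is internally consistent. Heights are plausible sex-specific
truncated normals (synthetic — the source table does not publish height).

Outcomes: the configured true logistic model's linear predictor is shifted
by a constant (solved by root-finding) so the cohort mean risk equals the
target event rate (default 91/1085 ≈ 8.39%), then ESTS events are
Bernoulli(pᵢ); each event patient receives one complication category drawn
at the published relative frequencies; increased pleural effusion is an
independent Bernoulli at 94/1085 ≈ 8.66%, mirroring its treatment as a
separate outcome category. The inclusion/exclusion filter runs in the
published order (inclusion criteria → non-lung-cancer pathology → missing
essential data) and returns an attrition table whose counts always sum to
the input size.

Covariates are sampled independently by default because only marginals are
published; a Gaussian-copula hook over the continuous covariates exists
(`copula_correlation`) but defaults off. Consequences worth stating: the
synthetic AUCs (~0.56–0.62) are lower than a real cohort would give,
because real covariate correlation (age–comorbidity, age–ppoFEV1%)
concentrates risk; passing tests demonstrate the *machinery* (scoring,
metrics, updating, reporting) and its statistical properties, not the
clinical performance of any model. The published table's extended-
resection rows read swapped (98.89% "yes" in a 97.7% VATS cohort); the
generator follows the narrative figure of 1.11% extended resections. The
published per-category complication counts sum to 91 while the text
describes one patient with three complications among 91 — the generator
models patient-level indicators (one category per event patient) and does
not attempt to resolve that accounting.

Default seed 20220209; every stochastic operation takes an explicit seed,
and any statistic of a generated cohort is reproducible bit-for-bit from
(config, seed).

## Problem sizes in the shipped tests

Deterministic oracles run at n ≤ 300 (brute-force AUC and threshold
scans); recovery simulations at n = 20000; the HL type-I simulation at
1000 replicates of n = 2000; generator marginals at n = 100000. These
sizes make every asserted tolerance comfortably attainable while keeping
the default suite under a minute on one core.

## Known limitations

- Thoracoscore and the modified Thoracoscore are not implemented (their
  required covariates are not in the cohort schema), nor are mortality
  models or any survival-time analysis.
- The 2019E1/Brunelli/aE1 registry entries are unverified transcriptions
  (flagged in provenance); the spirometry reference table is synthetic.
- No decision-curve analysis, O:E-ratio tests or AUC-difference tests.
- Model extension (adding predictors) and penalized updating are out of
  scope; so is any smoother-based calibration curve.
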