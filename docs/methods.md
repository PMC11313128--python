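# Methods

## The generating and analysis model

All components of the package share one multilevel model for a pupil's
outcome (minutes of weekday MVPA, whole-week MVPA, or sedentary time)
at measurement wave *t*:

    y_ijkt = mu + beta_g(yeargroup) + (gender/2)*g_k + b*(wear - wear_mean)
             + u_i + v_ij(t) + w_ijk(t) + e_ijkt

with study `i`, school `j`, pupil `k`; all random terms Gaussian and
mutually independent:

* `u_i ~ N(0, sigma2_study)` — constant over time;
* `v_ij(t)` — school effect, marginal variance `sigma2_school`,
  exchangeable (compound-symmetric) across waves with correlation
  **pi = CAC**;
* `w_ijk(t)` — pupil effect, marginal variance `sigma2_pupil`,
  exchangeable across waves with correlation **tau' (config `iac`)**;
* `e_ijkt ~ N(0, sigma2_resid)` i.i.d.

The within-study intra-cluster correlation is

    rho = sigma2_school / (sigma2_school + sigma2_pupil + sigma2_resid).

The exchangeable structure was chosen deliberately: empirical CACs for
school physical activity show no consistent decay over 1–5 year
follow-ups, and a single-parameter structure is exactly what the
stepped-wedge sample-size formulas consume.  Time-decaying correlation
models are out of scope (and are risky in design work: overconfident
short-lag correlations inflate apparent power).

### Study-level variance and the ICC denominator

The reported ICC excludes `sigma2_study` from its denominator (the
within-study school share).  A trial is run inside a single study
context, and planning SDs quoted for such trials are net of
between-study heterogeneity.  Whether study variance belongs in the
denominator is genuinely ambiguous when estimates come from pooled
multi-study data, so `icc_from_components(..., include_study=True)`
exposes the alternative.

## Synthetic data generator (`clusterpa.simulate`)

Defaults emulate pooled English school accelerometer studies:

| parameter | primary | secondary | meaning |
|---|---|---|---|
| grand_mean | 55.8 | 54.7 | weekday MVPA, min/day |
| sigma2_school | 43.06 | 37.81 | rho = 0.08 / 0.05 |
| sigma2_pupil | 277.2 | 406.5 | between-pupil |
| sigma2_resid | 217.98 | 311.94 | within-pupil |
| total within-study SD | 23.2 | 27.5 | sqrt of the rho denominator |
| sigma2_study | 54.5 | 12.4 | chosen so the marginal SD is ~24.8 / ~28.1 |
| cac | 0.6 | 0.6 | school-effect correlation |
| iac (config) | 0.7605 | 0.7731 | pupil-effect correlation, see below |
| gender_effect | 9 | 9 | boys − girls, min/day |
| missing_rate | 0.08 | 0.08 | MCAR per outcome cell |

The *observable* individual autocorrelation — the Pearson correlation
of one pupil's outcomes at two waves — includes every persistent
source: `(pi*s2_school + iac*s2_pupil + gender^2/4) / (total + gender^2/4)`.
The config `iac` values are calibrated so this observable correlation
is **0.46**.  Likewise the observable CAC (correlation of observed
school means of m pupils) is attenuated below pi by within-school
sampling error; `wave_pair_correlations()` returns both closed forms
and is the oracle used throughout the tests.

Other generator behaviour:

* Pupils advance one school year per elapsed year; a pupil crossing
  Y6 → Y7 moves to a new secondary school id drawn from a per-study
  destination pool.  This is what gives the CAC's same-school rule and
  the IAC's keep-the-movers rule something to act on.
* `valid_days` is drawn from a configurable distribution (default: 5%
  of rows below the two-day threshold); `filter_valid` applies the
  standard "at least two valid wear days" inclusion rule and reports
  the number of rows removed.
* Missingness is applied completely at random per outcome cell.  Real
  accelerometer missingness (4–20% depending on study) is unlikely to
  be strictly MCAR, but no mechanism is identifiable from marginal
  rates; this is an explicit simplification.
* Whole-week MVPA and sedentary time are affine transforms of the
  weekday-MVPA deviation (sedentary negatively signed), matched to the
  pooled means/SDs.  Cross-outcome correlation is therefore perfect
  and the ICC is identical across outcomes by construction — adequate
  for exercising per-outcome code paths, not for studying cross-outcome
  structure.
* Outcomes are truncated at zero (minutes cannot be negative).  At the
  default calibration ~1% of the Gaussian mass is affected; the induced
  attenuation of variances and correlations is an order of magnitude
  below the Monte-Carlo tolerances used in the tests.

What passing tests on these data show: the estimators recover the
parameters of *this* model.  They do not validate Gaussianity,
MCAR-ness, or exchangeability in real accelerometer data.

## Variance components and ICCs (`clusterpa.icc`)

Estimation is REML throughout (unbiased components at modest school
counts, and the convention of the major mixed-model packages).  The
model is fit by a purpose-built solver (`clusterpa.reml`) that exploits
the nested membership structure: the covariance is
`sigma2_e I + U D U'` with `U` the sparse study/school/pupil membership
matrix, so each likelihood evaluation costs one sparse factorisation of
a q × q matrix (q = number of random-effect levels) rather than
anything O(n²).  The log-variances are optimised by L-BFGS-B; the
covariance of the variance estimates is the inverse observed
information from a central finite-difference Hessian at the optimum.
The solver is cross-checked against statsmodels `MixedLM` (two-level
and three-level fits) in the test suite.

Details and conventions:

* Fixed effects: year-group (age) dummies and accelerometer wear time,
  centred at its sample mean.  The baseline-adjusted variant adds the
  pupil's previous outcome value as a covariate and refits on follow-up
  rows only.
* `by_yeargroup=True` gives each school year group its own independent
  school-variance parameter (diagonal random coefficients), one ICC per
  year group.
* A pupil random intercept is included whenever any pupil contributes
  repeated rows; with purely cross-sectional data the pupil and
  residual levels are a single within-school term.
* Single-study data: the study variance is reported as 0 with a
  warning rather than failing.
* Boundary fits (zero school variance) report ICC 0 with a one-sided
  upper bound instead of the (undefined) two-sided logit interval.
* Confidence intervals: delta method on the logit scale,
  `se_logit = se_icc / (icc (1 - icc))`, z = 1.959964 for 95%, then
  back-transformed — endpoints always inside (0, 1).
* Gender stratification refits per stratum; strata with fewer than two
  schools are skipped with a warning.

**Attenuation caveat.**  A school random *intercept* forced constant
over waves captures only the persistent share of school variance.  On
multi-wave data generated with CAC < 1 the pooled random-intercept ICC
is therefore biased toward `pi * rho`.  Per-year-group school
coefficients mitigate this (different waves mostly occupy different
year groups), and on single-wave data the estimand equals the
generating rho exactly — which is why the Monte-Carlo recovery checks
use cross-sectional replicates.

## Autocorrelations (`clusterpa.autocorr`)

One `CorrelationRecord` per study × wave-pair × level:

* **school**: Pearson correlation of per-school mean pairs; schools
  need ≥ 5 contributing pupils at each wave, and only unchanged school
  ids pair up (movers drop out);
* **pupil**: Pearson correlation over pupils with both measurements,
  movers retained.

Records are Fisher-transformed (`z = arctanh r`, variance `1/(n-3)`,
hence the n ≥ 4 floor), pooled by inverse-variance weights within
follow-up bins (integer years; follow-ups under a year form their own
bin), and back-transformed.  Random-effects pooling is
DerSimonian–Laird with tau² floored at zero — implemented directly,
since the available library routine does not apply the floor — with
fixed-effect pooling as an option; the pooled z, its normal-theory CI,
tau² and Q are reported.  The finite-m attenuation of the CAC is
reported as-is, not corrected: design calculations conventionally use
raw observed school-mean correlations.

## Trial design (`clusterpa.design`)

*Parallel cluster RCT.*  Equal allocation, design effect
`DE = 1 + (m-1) rho`, SE of the arm difference
`sqrt(2 sigma^2 DE / (k m))`.  The per-arm count k is the smallest
integer whose two-sided t test with df = 2(k−1) reaches the target
power (noncentral-t power; the df depend on k, hence the iteration).
The t-correction typically adds one school per arm over the normal
approximation and matches the behaviour of the standard cluster-power
packages.  The baseline-adjusted variant runs the identical algorithm
on baseline-adjusted sigma and rho — supplying *both* adjusted inputs
matters; mixing adjusted and unadjusted quantities mis-sizes the trial.

*Stepped wedge.*  Complete design: S sequences, T = S+1 periods, an
all-control first period, sequence s crossing over at period s, equal
allocation (totals rounded up to a multiple of S).  Cluster-period
means follow the exchangeable model with the `v_between` / `v_within`
split quoted in the README; a closed cohort adds the IAC share of the
pupil variance to the persistent component.  The treatment-effect
variance is the closed-form Hussey–Hughes GLS expression (verified to
1e-8 against explicit covariance inversion), power uses normal critical
values (standard for this variance, and consistent with the reference
school counts), and a candidate size is accepted when power ≥ target
(non-strict, which decides near-ties).  Power at δ = 0 is reported as
alpha exactly; elsewhere the negligible wrong-tail rejection mass is
ignored.

*Mis-specification analysis.*  `achieved_power(spec, n, true_icc=...)`
evaluates a sized design under a different true ICC — the "sized at
0.04, true 0.08, 64% power" style of audit.

Out of scope by design: unequal cluster sizes, attrition inflation,
open cohorts, and decaying-correlation sample size formulas.

## Numerical choices

* REML optimisation over log-variances, bounds `[1e-8, 50] * var(y)`;
  a component at the lower bound is reported as exactly 0 (boundary).
* Finite-difference Hessian steps `max(1e-3 * var, 1e-7 * var(y))` per
  component; tiny negative diagonal from FD noise is ridge-repaired.
* Sparse LU (`splu`) is used once q > 400, dense Cholesky below.
* Pearson correlations via `scipy.stats.pearsonr`; meta-analysis z
  critical value 1.959964 as elsewhere.
* Pipeline determinism: the global seed is expanded into per-stage
  substreams via `SeedSequence` with CRC-32 stage tags, so reruns are
  byte-identical and stages can be rerun in isolation.

## Monte-Carlo problem sizes in the test suite

Recovery and coverage checks are sized to be informative yet quick:
ICC bias uses 200 cross-sectional replicates of 50 schools × 25 pupils;
interval coverage uses 200 replicates at 500 schools (binomial
simulation error ±4.6 percentage points at 95%); CAC/IAC recovery uses
one 5-study, two-wave dataset of 40 schools × 25 pupils per study with
3-Monte-Carlo-SE tolerances against the closed-form wave-pair
correlations.  With three or more waves the wave-pair records within a
study share schools, so independence-based pooled SEs understate the
Monte-Carlo error; the recovery dataset therefore uses a single wave
pair per study.

## Known limitations

* Class-level clustering cannot be separated from school-level
  clustering; reported ICCs combine both.
* The REML solver assumes pupils are nested in schools within any one
  fit; pooled primary+secondary fits spanning the school transition
  violate this, so fits should be run per phase (as the estimation
  pipeline does via year-group coefficients) — the generator's movers
  exist to exercise the *autocorrelation* rules, not cross-phase ICC
  fits.
* Non-Gaussian outcomes (e.g. heavily right-skewed self-report MVPA)
  are not modelled; ICCs on transformed scales are deliberately not
  offered.
* The empirical CAC remains imprecise at realistic school counts; wide
  pooled intervals are a property of the estimand, not an estimator
  defect.
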