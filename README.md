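# clusterpa

Design school-based cluster trials of children's physical activity.

School programmes to increase children's moderate-to-vigorous physical
activity (MVPA) are evaluated with cluster-based designs — parallel
cluster RCTs and, increasingly, stepped wedge designs — because the
intervention acts on whole schools.  Sizing such a trial needs three
correlations that are properties of the population, not the design:

* **ICC (ρ)** — the intra-cluster correlation, the share of outcome
  variance lying between schools;
* **CAC (π)** — the cluster autocorrelation, how strongly a school's
  mean outcome persists between two measurement occasions;
* **IAC (τ)** — the individual autocorrelation, how strongly a pupil's
  own outcome persists between occasions.

`clusterpa` provides the full chain a methodologist needs to work with
these quantities on multilevel accelerometer data (pupils nested in
schools nested in studies, with repeated waves):

1. **`clusterpa.simulate`** — a multilevel longitudinal data generator
   with known ρ, π, τ and closed-form moments, calibrated to pooled
   English school accelerometer data (weekday MVPA ≈ 55.8 ± 24.8
   min/day in primary schools), plus the standard "at least two valid
   wear days" inclusion filter.
2. **`clusterpa.icc`** — REML estimation of study / school / pupil /
   residual variance components (a bespoke sparse solver for the nested
   three-level model), per-year-group ICCs, delta-method 95% intervals
   on the logit scale, gender stratification, and a baseline-adjusted
   (ANCOVA-style) variant.
3. **`clusterpa.autocorr`** — empirical CACs (same-school Pearson
   correlations of school means, schools with < 5 pupils excluded) and
   IACs (pupil-level correlations, school movers retained), pooled over
   studies and follow-up lengths by Fisher-z inverse-variance
   meta-analysis (DerSimonian–Laird random effects).
4. **`clusterpa.design`** — sample-size and power calculators for six
   designs: two-arm cluster RCT (design effect 1 + (m−1)ρ with the
   iterative t-correction, df = 2(k−1)), baseline-adjusted cluster RCT,
   and cross-sectional / closed-cohort stepped wedges with S steps
   built on the Hussey–Hughes closed-form GLS treatment variance with
   cluster-period variance components

       v_between = π ρ σ² (+ τ (1−ρ) σ²/m for a cohort)
       v_within  = (1−π) ρ σ² + (1−τ·cohort) (1−ρ) σ²/m.

5. **`clusterpa.pipeline` / the `clusterpa` CLI** — a seeded,
   logged simulate → filter → estimate → design pipeline.

## Worked example

Size a primary-school trial to detect a 5-minute increase in weekday
MVPA (total SD 23.2 min, 25 pupils per school, ICC 0.08, 80% power, 5%
two-sided α):

```bash
$ clusterpa design --design crct --delta 5 --sd 23.2 --icc 0.08 --m 25
total schools: 82  allocation: (41, 41)  achieved power: 0.8053

$ clusterpa design --design sw-cohort --steps 2 --delta 5 --sd 23.2 \
      --icc 0.08 --cac 0.6 --iac 0.5 --m 25
total schools: 48  allocation: (24, 24)  achieved power: 0.8130
```

The parallel cRCT needs 82 schools; a two-step cohort stepped wedge —
which reuses both schools (CAC 0.6) and pupils (IAC 0.5) across
periods — reaches the same power with 48.  Mis-specifying the ICC is
costly: a trial sized with ρ = 0.04 instead of 0.08 would recruit only
56 schools and actually run at 64% power:

```bash
$ clusterpa design --design crct --delta 5 --sd 23.2 --icc 0.08 --m 25 --power-at 56
power at 56 schools: 0.6396
```

`clusterpa report` prints the whole planning grid (five designs ×
primary/secondary × point/upper-bound ICC):

```text
                          primary_point  primary_upper  secondary_point  secondary_upper
crct                                 82             94               68               96
sw_cross_sectional_2step             62             68               50               64
sw_cohort_2step                      48             54               40               54
sw_cross_sectional_3step             39             42               30               39
sw_cohort_3step                      30             33               24               33
```

The same computations are available as library calls
(`required_schools`, `achieved_power`, `planning_table`), and the
estimation side runs from any observation CSV via
`clusterpa icc`, `clusterpa autocorr` or a YAML-configured
`clusterpa run`.

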