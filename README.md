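# apcbounds

Bounded age-period-cohort (APC) analysis of survey-weighted time-diary
microdata, with a synthetic-data generator for validating every stage
against known ground truth.

## The problem

Person-day diary records (for example, minutes spent alone in nonwork
activities) pooled over many survey years confound three clocks: **age**
(life-course change), **period** (society-wide change at the diary date),
and **cohort** (differences between birth generations). Because
`Age = Period − Cohort`, the three *linear* trends are not separately
identifiable: for grouped data with centered linear contrasts,
`P_L = A_L + C_L` holds record-for-record, and only two linear combinations
are estimable,

```
theta1 = alpha_L + pi_L        theta2 = gamma_L + pi_L
```

together with *all* nonlinear deviations. The estimable model fitted here
by survey-weighted least squares is

```
y_i = b0 + theta1*A_iL + theta2*C_iL
         + alpha_NL'A_i + pi_NL'P_i + gamma_NL'C_i + beta'x_i + e_i
```

where the factor columns are **weighted orthogonal polynomial contrasts**
(orthogonalized under the survey-weight inner product, truncated at order
5) so that linear and nonlinear effects stay independent despite unequal
group sizes, and `x_i` holds day-of-week and holiday contrasts in
weighted-effect coding.

The linear effect triples consistent with the data form the **canonical
solution line** `(theta1 − pi, pi, theta2 − pi)`. A substantive constraint —
people spend the least time alone in their mid-30s, so the net total age
curve must attain its minimum at the group containing age 35 — is imposed
by a grid search over candidate linear age effects. The accepted extremes
bound a segment of the line (a **bounded region** with equal-width ranges
for the three linear effects), and each dimension's **net total effect
curve** (chosen linear effect + fitted nonlinearities, in mean minutes per
day) is reported with the identification band swept out by that region.

The package is written for researchers analysing grouped APC data from
repeated cross-sectional surveys (time-use, health, attitudes) who want
partial-identification bounds rather than an arbitrary equality constraint.

## Worked example

```python
import apcbounds as ab

config = ab.SimConfig(seed=1, n_records=50_000)          # men-like defaults
table = ab.simulate_microdata(config)
print("truth: theta1, theta2 =", ab.true_identifiable_params(config))

analysis = ab.BoundedAPCAnalysis().fit(table)
print(f"theta1 = {analysis.theta1_:.3f}, theta2 = {analysis.theta2_:.3f}")
lo, hi = analysis.alpha_range_
print(f"accepted linear age effects: [{lo:.2f}, {hi:.2f}]")
s = analysis.summaries_["age"]
print(f"net age curve: min {s['min_mid']:.0f} min at {s['argmin_group']}, "
      f"max {s['max_mid']:.0f} min at {s['argmax_group']}, gap {s['gap']:.0f}")
```

prints

```
truth: theta1, theta2 = (4.199999999999999, 0.3999999999999999)
theta1 = 4.041, theta2 = 0.263
accepted linear age effects: [2.41, 3.75]
net age curve: min 287 min at 35-39, max 333 min at 75-79, gap 46
```

The generator's defaults encode a linear triple (2.8, 1.4, −1.0) minutes
per five-year group step, so the identified parameters are theta1 = 4.2 and
theta2 = 0.4; this single draw (n = 50,000, residual sd 60 minutes)
recovers them to within sampling error. The accepted interval [2.41, 3.75]
is the set of linear age effects whose net total age curve bottoms out in
the 35-39 group; it covers the generating value 2.8. The net age curve has
its minimum at the 35-39 group by construction of the constraint and rises
to its maximum at the oldest ages.

The same analysis runs from the shell:

```bash
apcbounds simulate --out data.csv --seed 1 --n 50000
apcbounds fit --data data.csv --out results/
apcbounds report --results results/ --out net_effects.png
```

`fit` writes, per gender stratum, `estimates.json`, `canonical_line.csv`,
`bounded_region.json`, `net_effects.csv`, `summaries.json`,
`descriptives.csv`, and a `manifest.json` with the full configuration and
row counts. Weekday/weekend and restricted-year sensitivity analyses are
pure configuration changes (`FilterSpec(day_subset=...)`,
`FilterSpec(year_range=(2003, 2019))`).

To analyse real survey extracts instead of simulations, flatten them to
the canonical CSV schema (`age, year, cohort_year?, gender, minutes_alone,
weight, day_of_week, holiday`); see `docs/methods.md` for the validation
rules.

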