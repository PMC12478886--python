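# Methods

## Model

Each record is one person-day: outcome `y` in minutes (bounded to
[0, 1440] at validation), a positive survey weight `w`, age in years,
diary year, gender, day of week, and a holiday flag. Ages and years are
binned into equal-width groups (defaults: 13 five-year age groups from 15,
4 five-year periods from 2003); cohort is the Lexis diagonal
`cohort_idx = period_idx − age_idx + (n_age − 1)`, giving
`n_age + n_period − 1` groups (16 by default, labelled by the birth-year
span of each diagonal, e.g. 1924-1932).

The mean model is additive in the three factors and the covariates:

    y = b0 + alpha_L*A_L + pi_L*P_L + gamma_L*C_L
           + alpha_NL'A + pi_NL'P + gamma_NL'C + beta'x + e

with each factor represented by weighted orthogonal polynomial contrasts
of the 0-based group index. Because the centered linear contrasts satisfy
`P_L = A_L + C_L` exactly on the Lexis surface, the model is reparameterized
with `theta1 = alpha_L + pi_L` on `A_L` and `theta2 = gamma_L + pi_L` on
`C_L`, and `P_L` is excluded; this reparameterized model is estimable and
is fitted by weighted least squares (statsmodels WLS on the documented
design; an independent normal-equations solve serves as a test oracle).
With defaults the design has 20 columns: intercept, A_L, C_L, age
polynomials 2-5, period polynomials 2-3, cohort polynomials 2-5, six
day-of-week contrasts, one holiday contrast.

### Contrast construction

Group weights are the per-group sums of survey weights (case counts are a
config option). Contrasts come from Gram-Schmidt on the monomials
`1, g, g^2, ...` under the inner product `<u,v> = sum_g (w_g/W) u_g v_g`.
Choices that matter:

* **Linear scale.** The linear contrast is the weighted-centered group
  index itself — slope 1 per group step — so linear coefficients read as
  minutes per five-year step. A per-year scale (divide by the group width)
  is available via `linear_scale="year"`.
* **Nonlinear normalization.** Orders 2..min(5, G−1) are normalized to
  unit weighted RMS. Any fixed normalization yields identical fitted
  values (verified in tests); coefficients are always reported with their
  basis so they are interpretable.
* **Truncation.** Polynomial orders beyond 5 are omitted to smooth the
  group curves; for the 4 period groups the cap is G−1 = 3.
* **Covariates.** Day-of-week and holiday use weighted-effect coding
  (weighted mean zero; Sunday and non-holiday are the dropped levels), so
  the intercept is the weighted grand mean and net-effect curves need no
  further covariate adjustment. Only day levels present in the fitted
  table receive columns, which lets weekday- or weekend-only sensitivity
  analyses run with no code change.

### Bounding

`theta1`/`theta2` fix the canonical solution line
`(theta1 − pi, pi, theta2 − pi)`. The substantive constraint is that the
net total age curve — `alpha*A_L + age nonlinearities`, intercept-free —
attains its minimum at the age group containing 35 (35-39, index 4). A
grid search over candidate `alpha` (defaults −20..20, step 0.01 minutes
per group step, wide enough to bracket any plausible slope) accepts a
candidate when the target group's value is within a relative tolerance of
1e−9 of the curve minimum (`tie_policy="target_attains_min"`; a strict
`unique_argmin` policy is available — with 13 groups, exact ties at machine
precision are otherwise possible, e.g. the all-zero curve). The accepted
extremes give `alpha_range`; period and cohort ranges follow with slope
±1 along the line, and the midpoint triple sits at the center. If no
candidate is accepted the search raises, reporting the argmin group at the
grid ends and at zero for diagnosis.

### Net total effects

For each dimension, the curve at linear value `v` is
`b0 + v*linear_g + sum_k coef_k*contrast_kg`: mean minutes per day for an
average day-of-week/holiday mix with the other two dimensions at their
weighted-effect zero. The mid curve uses the region midpoint; because the
curve is affine in `v`, the min/max band is the envelope over the two
range endpoints, and the band width at group `g` is exactly
`|range width| * |linear_g|` (zero where the centered linear contrast
vanishes). Bands represent identification uncertainty only — no sampling
uncertainty is quantified anywhere in v1, and argmin ties resolve to the
lowest group index.

## Synthetic data generator

`SimConfig`/`simulate_microdata` emulate a pooled cross-sectional diary
sample: ages and years drawn per the configured cell density (uniform by
default; an age-skewed option emulates unequal cell sizes), cohort = year −
age exactly, i.i.d. lognormal(0, 0.5) survey weights (constant available),
uniform day of week, Bernoulli(0.03) holidays, Gaussian residual noise.
Defaults are a men-like configuration: grand mean 300 minutes, linear
triple (2.8, 1.4, −1.0) per group step, a U-shaped age quadratic (8.7 on
the unit-RMS basis — placing the net-age vertex at the 35-39 group under
the default linear age effect), a mirrored cohort quadratic (6.0), a mild
period acceleration (1.2, 0.8), weekday/weekend contrasts of tens of
minutes, holiday effect −40, noise sd 60 minutes.

Two design decisions make the generator a sharp oracle rather than an
approximate one:

* Ground-truth nonlinear coefficients are defined **on the realized
  sample's own weighted contrast bases** (regenerated per draw), and the
  covariate effects are centered by the realized weights. At zero noise,
  fitting therefore recovers every coefficient to machine precision
  (verified to ~1e−14), and `expected_group_means` — the weighted group
  means of the noise-free outcome surface — is exact, not asymptotic.
* All random draws are made before, and independently of, the effect
  parameters, so configurations that differ only along the null direction
  (+d, −d, +d) share every variate: the formal unidentifiability is
  visible as data invariance. The invariance is exact up to float
  rounding of the shifted coefficients (a few ULPs of ~300 minutes;
  bitwise equality of the sums is not representable in IEEE 754, e.g.
  fl((2.8+17)+(1.4−17)) ≠ fl(2.8+1.4)).

The outcome is *not* clamped to [0, 1440] by default: clamping censors the
tails and would bias recovery comparisons. A `clamp_outcome=True` mode
exists for realistic-looking data and is documented as biased.

What the generator does **not** emulate: diary episode structure,
within-person correlation across panel days, heteroskedastic or
heavy-tailed residuals, seasonality within years, non-response patterns,
or any correlation between weights and the outcome. Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the stated sampling model, not robustness to real-survey complications.

## Numerical choices and problem sizes

* WLS via QR on the weight-scaled design; rank problems are detected by
  the condition number of the scaled design (limit 1e10) after explicit
  checks for empty groups and missing covariate levels.
* Contrast orthogonality holds to <1e−10 in the weighted Gram matrix
  across random weight vectors; basis construction is invariant to
  rescaling all weights.
* The recovery study used in tests and in the acceptance script runs 20
  replicates of n = 50,000 (a size at which a full fit takes well under a
  second, and which yields per-replicate sampling sd ≈ 0.21 for theta1).
  Identification-driven collinearity is intrinsic here: with 13 age and 4
  period groups, corr(A_L, C_L) ≈ −0.96, so theta SEs are ≈3.5× the naive
  no-collinearity value — the dominant driver of the spread of recovered
  linear effects and of replicate-to-replicate variation in the accepted
  alpha interval (whose placement also responds to noise in the order-3..5
  age coefficients).
* Grid bounds are reported at grid resolution (0.01 by default); halving
  the step moves bounds by at most one original step.

## Known limitations

* Single-year (ungrouped) APC designs and unequal group widths are out of
  scope; the grouping must tile the configured age/year ranges exactly.
* Only the single argmin-location constraint family is implemented;
  monotonicity or sign constraints on other dimensions are not.
* No survey-design (replicate-weight) variance estimation; residual sd
  and the design condition number are the only fit diagnostics surfaced.
* The descriptive weighted group-mean curves are raw means by single year
  of age/period/cohort; no smoothing is applied.
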