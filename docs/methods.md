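# Methods

## Scope and model

`pensiongap` estimates the old-age mortality gradient by pension income from
individual pensioner records.  The estimand set is: graduated death
probabilities q_x by single age x ∈ [65, 101], pension-income (PI) group and
calendar period; relative mortality ratios by 5-year age group; complete
period life tables with LE₆₅ and LE₇₅, their variances and 95% CIs;
one-tailed tests of LE differences between PI groups; mortality improvements
between periods; and the High–Low LE-gap trend.

The population concept is male general-regime retirement pensioners who
entered at the statutory age (65 or later).  All other record types reach
the pipeline only to be counted by the exclusion cascade.

## Synthetic registry

The generator emulates the administrative register the analysis is designed
for, with one row per beneficiary: sex, birth date, pension start/end dates,
benefit type, scheme, retirement age, initial monthly pension (EUR), death
date or censoring, at day resolution (ISO-8601).  Its key properties:

* **Mortality.** Remaining lifetime from pension entry follows a PI-group
  specific Gompertz–Makeham hazard μ(x) = a + b·cˣ, sampled by inverting the
  analytic cumulative hazard (closed form when a = 0, otherwise a 60-step
  bisection, accurate to < 1e-8 years).  Defaults: a = 2e-4/yr, c = 1.11,
  and b chosen per group (1.342e-5, 1.207e-5, 1.073e-5, 9.683e-6) so that
  true remaining life expectancy at 65 is 18.3 / 19.1 / 20.0 / 20.8 years —
  a Low-to-High gap of 2.5 years, the magnitude reported for Spanish male
  retirement pensioners.  `true_life_expectancy` integrates the survival
  function (trapezoid, step 0.01 y, horizon age 120) and is the recovery
  target everywhere; an apparent corner case: b = 0 is accepted as a pure
  constant hazard (c is then ignored), while b < 0 or c ≤ 1 with b > 0 are
  rejected.
* **Entries and censoring.** Pension start dates are uniform over
  `entry_year_range` (default: 36 years before the observation window to its
  end), so all ages 65–101 are exposed inside the window; deaths after the
  window end are emitted as censored (empty death date), emulating
  pensioners alive at the last register wave.
* **Group sizes.** Default group weights (0.13, 0.47, 0.16, 0.24) mirror the
  register's exposure shares.
* **Pension amounts.** Lognormal per group, truncated to the group's
  classification interval, so ground-truth group labels are recovered
  exactly by the classifier; after rounding to cents, amounts are clamped to
  the nearest cent strictly inside the half-open interval so boundary draws
  cannot leak into a neighbouring group.  The lognormal shape is a stand-in:
  no distributional form for within-group pensions is available, and nothing
  downstream depends on it beyond the group label.
* **Contamination.** Each record receives at most one defect class, drawn
  categorically with the configured rates (defaults mirror a real register
  wave: 50.8% female, 19.4% non-retirement, 13.2% early retirement, 6.9%
  special scheme, 0.2% administrative error, 0.08% invalid birth date).
  Every defect is observable in the record (e.g. administrative errors
  manifest as a pension closed before it opened) and also carried as a
  hidden ground-truth label, so the cascade can be audited exactly.

What the generator does **not** emulate: month-resolution pension dates
(real registers often store month/year; we keep days and let tabulation
decide), duplicate records, within-group mortality heterogeneity, period
effects (hazards are time-constant unless configured otherwise), migration,
or benefit revaluation.  Passing tests therefore demonstrate correctness of
the estimation machinery under a clean data-generating process, not
robustness to every real-register pathology.

## Exclusion cascade and classification

Exclusions are applied in a fixed precedence order — invalid birth date,
female, non-retirement benefit, administrative error, deceased before the
reference period, early retirement (benefit type `early_retirement` or
retirement age < 65), special scheme, other technical (entry after the
reference period) — and a record failing several rules increments only the
first counter, which makes the report conserve counts by construction.
Unparseable rows are counted (under invalid birth date or administrative
error depending on the field), never silently dropped.

PI groups use the legal minimum and maximum benefits in force in the
retirement year, supplied as a year → (Min, Max) table with nearest-year
fallback; the Min is the single-pensioner minimum (configurable).  The
Med-Low upper cutoff uses the coefficient 0.33 literally, not 1/3.  Groups
are assigned once, at retirement.

## Exposure and deaths

Age basis is age last birthday.  A record accrues exposure at age x from
max(pension start, period start, x-th birthday) to min(death, pension end +
1 day, period end + 1 day) intersected with the x+1-th birthday, in days
divided by 365.25.  Age intervals are half-open [birthday, next birthday),
so a death on an exact birthday belongs to the age just attained and such a
record contributes zero exposure at that age.  Feb-29 birthdays fall to
Mar 1 in non-leap years.  Exposure and deaths above age 101 pool into the
101 cell, which therefore represents the open interval 101+.

## Graduation

The primary smoother is a penalized Poisson B-spline regression:
D_x ~ Poisson(E_x·exp(η_x)), η a cubic B-spline expansion on equidistant
knots (one interior knot per 2 years of age), with a second-order difference
penalty on the coefficients.  Fitting is by IRLS to a relative coefficient
change below 1e-6 (cap 200 iterations; failure raises with the iteration
history).  The smoothing parameter is selected by BIC
(deviance + log n · edf, edf the trace of the hat matrix) over a log-spaced
grid 1e-4…1e7.  η is clipped to [−40, 10] for numerical safety, and a
smoothing value whose IRLS step produces a singular system is treated as
non-converged and skipped by the grid search.  With all-zero deaths the
penalized fit is returned as-is with a warning.  Limits used as oracles in
the tests: with knots at every age and λ → 0 the fit reproduces crude rates
where E_x > 0; with λ → ∞ the order-2 penalty leaves exactly a log-linear
rate schedule.

The robustness check is a discrete beta kernel smoother: the graduated rate
at age x is the kernel-weighted mean of crude rates, the kernel a beta
density on the normalized age interval with mode at x (its shape adapts near
the boundaries, avoiding edge bias); the bandwidth is user-set or chosen by
exposure-weighted leave-one-out cross-validation.

Central rates convert to probabilities by q = 1 − e^{−m} (constant force
within the year of age).  Each (group, period) series is graduated
independently, and the Total series is graduated from its own pooled deaths
and exposures rather than by averaging group fits; relative mortality can
alternatively use the exposure-weighted mean of group rates as denominator
(`total_mode="weighted"`), under which the exposure-weighted mean RM is
exactly 1.

## Life tables and inference

Standard period life-table recursion, radix l₆₅ = 100,000, separation factor
a_x = 0.5 for ages 65–100, closeout q₁₀₁ = 1 with L₁₀₁ = l₁₀₁/m₁₀₁.
Because the 101 cell pools all exposure and deaths of the open interval,
1/m₁₀₁ is the standard open-age estimate of remaining expectancy there; an
earlier capped variant (a₁₀₁ ≤ 1) produced a small systematic LE deficit and
was dropped.  When no closeout rate is available (probability-only input)
the open interval contributes 1.0 year.

Variances follow Chiang's method: var(q_x) = q_x²(1−q_x)/D_x with
D_x = E_x·m_x the estimated deaths (algebraically the binomial form with
effective trials ≈ E_x), propagated as
var(e_a) = Σ l_x²(0.5 + e_{x+1})² var(q_x) / l_a², the closeout age carrying
no variance term (its weight l₁₀₁² is negligible at these radices).  A
500-replicate record-level bootstrap — resample records, re-tabulate,
re-graduate at the point estimate's smoothing value, rebuild the table —
reproduces the Chiang 95% CI width to within a few percent, which is the
calibration evidence for this choice.  LE differences are tested one-tailed
(richer minus poorer) with z = ΔLE/SE, flags at z > 2.326 (1%), 1.645 (5%),
1.282 (10%).

## Inequality statistics

Age-group rates are exposure-weighted means of graduated q over the bins
65–69, 70–74, 75–79, 80–84, 85+ (pooled to 101) and Total.  Relative
mortality is the ratio of a group's bin rate to the Total bin rate; values
are kept at full precision internally and rounded to 2 decimals only for
presentation, where the Dif Low-High column is recomputed from the rounded
ratios (matching how such tables are printed).  Mortality improvements
between two periods are 100·(1 − Σw·q_later / Σw·q_earlier); the weights are
the earlier period's exposures by default (a fixed Laspeyres-style
standard), switchable to the later period's — with pooled calendar years per
period neither convention is canonically right, so both are exposed.  The
gap trend reports per-period High–Low LE gaps and their OLS slope over the
period index.

## Problem sizes and numerical choices

The test suite and acceptance script choose simulation sizes so each check
is informative at desk scale: hazard-recovery checks use 200,000 records
(3-Poisson-SE bands at single ages), the LE-recovery check uses 50,000
records per group with the mean error over 3 fixed replicates compared to a
±0.15-year band (a single replicate's Monte Carlo SE, ~0.075 y, would make
one draw uninformative about bias), the gap-power check runs 50 replicates
of a two-group design with a true 2.5-year gap, and the bootstrap
calibration uses 500 replicates on a 50,000-record group.  Monte Carlo
tolerances in tests are derived from the realized death counts
(relative SE ≈ 1/√deaths) rather than fixed by hand.

## Known limitations

* The variance of LE ignores smoothing-induced correlation between ages;
  the bootstrap check shows this is immaterial for LE but it would matter
  for functionals of individual q_x.
* Exposure is computed at day resolution; registers storing month/year
  pension dates would need a documented imputation convention first.
* The beta-kernel route smooths crude rates directly and ignores the
  Poisson weighting of cells; it is a cross-check, not the estimator.
* Period life tables mix cohorts by construction; no cohort tables or
  rate projections are provided.
* RM tables require every age bin to carry exposure for every group; very
  small groups should be pooled upstream instead.
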