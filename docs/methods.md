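# Methods

## Scope and data model

The package projects malignant mesothelioma incidence from three inputs:
registry case counts by sex × age group × calendar time, person-years of
population at risk on the same axes, and an annual asbestos consumption
series. Annual resolution is canonical; 5-year binning is always an
explicit operation (`aggregate_to_bins`), never implicit. Age intervals
are closed-open with an optional open-ended top group; a period label
"2014–2018" covers both endpoint years. Crude rates are reported per
100,000 person-years, the registry convention for rare cancers.

## Power-link APC model

Rates on a Lexis grid (A age groups × P periods, cohorts on the
diagonals, `c = A − a + p`) are modelled as
`R_ap = (A_a + D·p + P_p + C_c)^power` with `power = 5`. The fifth-root
link is the standard long-range projection choice: on the fifth-root
scale a linear trend grows much more slowly than on the log scale.

**Identifiability.** Only the linear time trend is non-identified in an
APC decomposition. We adopt the NORDPRED convention: `P` and `C` are
constrained to zero sum and zero linear slope (implemented by
parametrising them in an orthonormal null-space basis of those two
constraints), so the drift `D` carries the entire linear trend. A gauge
test verifies that moving a linear-in-`p` component between `P` and
`(D, A)` leaves fitted rates unchanged.

**Fitting.** Iteratively reweighted least squares on the fifth-root
scale with Poisson weights: observed rates `y = cases/N` enter through
the working response `z = η + (y − η^5)/(5η^4)` with weights
`25·N·η^3`, started from the age-only model (pooled age-specific rates),
with step-halving so the Poisson deviance decreases monotonically;
convergence at deviance change < 1e−8 or 100 iterations. The linear
predictor is floored at 1e−4 (rate 1e−20) to keep the link derivatives
finite; cells with zero person-years are rejected rather than imputed.
A test cross-checks deviance and drift against a statsmodels GLM with a
`Power(0.2)` link and person-years variance weights (agreement ~1e−9).

**Projection.** For future period `P + k` the drift increment beyond the
last observed period is `D·Σ_{j≤k} att_j` with cut-trend multipliers
`att = (1, 0.75, 0.5, 0.25)` by default (configurable; the horizon may
not exceed the schedule). The period effect is frozen at `P_P`; cohorts
beyond the last estimated level reuse that level. A negative linear
predictor truncates the rate to zero. `drift_mode="recent"` replaces the
extrapolated step by `D + (P_P − P_{P−1})`, the slope of the last two
observed periods. Sexes are always fitted and projected independently.

**Age binning.** The APC analysis uses 5-year age groups 0–4 … 85+ (18
groups) — the NORDPRED convention; the exposure model uses the coarser
0–39, 40–49, …, 80+ grouping (baseline 0–39).

## Cumulative exposure covariate

Sparse trade checkpoints (production, imports, exports) are linearly
interpolated to annual series per component — exact at checkpoints, no
extrapolation outside the span. Net consumption is
production + imports − exports, clamped at zero with a warning when
exports exceed supply (stockpile drawdown); per-capita consumption is
tonnes × 1000 / total population.

For an age group with representative age `a` (interval midpoint; 20 for
0–39, 85 for 80+) observed in year `Y`, the covariate is
`(Σ_{t=Y−a}^{Y−L_t} C(t)) · e/d` with latency `L_t = 40` years, `e` the
window length in years and `d` the number of window years with data: a
mean-imputation of missing years. This reading of `e/d` is the only one
that is dimensionally coherent as a missing-data rescaling; it is
isolated in a single function (`cumulative_exposure`) so it can be
swapped. Ages below the latency get exposure 0; a window with no data at
all is an error, but years before the first recorded consumption year
can be declared zero (`assume_zero_before`), reflecting negligible
pre-industrial use. The exposure series is shared across sexes.

## Poisson regression

The design has columns const, exposure, sex (0 = women, 1 = men), age
dummies for every non-baseline group, and sex×age interactions — for 6
age groups, 13 columns. There is no person-years offset by default: the
reference formulation models counts, not rates (an offset mode exists as
an option). Fitting is a standard Poisson GLM with log link, delegated
to statsmodels IRLS; standard errors come from the observed information
and are diagnostics only. Zero-count cells are retained. At the optimum
the intercept score equation makes total predicted counts equal total
observed counts, which is asserted in tests.

## Validation and selection

`E/O` ratios use the normal approximation to the Poisson distribution of
O: `(E/O)·exp(±z·√(1/O))`, z = 1.96 at α = 0.05, exactly log-symmetric.
The count inside the CI formula is kept as a separate field
(`observed_ci`) because some published tables computed every stratum CI
with the pooled O; default behaviour uses the stratum's own O. Selection
minimises |ratio − 1| on the natural scale (log-scale distance is an
option); equal distances within 1e−9 raise a tie flag rather than
picking silently. Table ratios are rounded half-away-from-zero to 3
decimals at report time only.

## Synthetic worlds

The generators are first-class, tested code standing in for
non-redistributable registry extracts.

* **APC world** (default): 18 five-year age groups × 4 periods from
  1994, total population 50M split evenly by sex across a smooth,
  middle-heavy pyramid; age-specific rates rising from ~0.01 to ~2.6 per
  100,000 (a mesothelioma-like age curve); drift 0.008 per period on the
  fifth-root scale, which roughly triples counts over four periods —
  matching the observed growth of a registry of this size (male counts a
  few hundred per 5-year period). Female rates are scaled by 0.87 on the
  fifth-root scale (≈ half the male rate). Counts are independent
  Poisson draws per cell; `annual=True` splits person-years evenly
  within periods so the binning step is exercised.
* **Consumption world**: piecewise-linear rise from zero in 1940 to a
  95 kt peak in 1992, linear decline to zero at the 2009 ban — the
  recorded shape of Korean consumption at national scale. Thinning to
  checkpoints that include the kink years makes interpolation exactly
  recoverable.
* **Exposure world**: annual counts for 6 coarse age groups, 1994–2018,
  drawn Poisson from the log-linear model with β_exposure = 0.05 per
  kg·year/person and age/sex effects sized so totals are registry-like
  (hundreds to low thousands per year).

Scenario defaults were fixed on these realism grounds before any
acceptance measurement and are mandatory-seed pure functions. What a
green test establishes: the fitters recover the parameters of their own
generating processes and the validation layer prefers the correctly
specified model. What it does not establish: anything about registration
completeness, diagnostic drift, occupational vs environmental exposure
mix, or other real-data features the generators deliberately omit.

## Numerical and design choices

* Drift-recovery tolerance (|D̂ − D| < 0.002 at the default 18×4
  large-person-years scenario) was frozen from a one-off Monte-Carlo
  experiment: 40 independent fits gave SD ≈ 3.7e−4 with bias ≈ 1.6e−4;
  the tolerance is bias + 4·SD.
* The published age-stratum table's totals row repeats the per-sex
  ratios instead of E/O of its own printed pair; reproduction tests
  cover the per-sex rows and all age-stratum rows, not the totals row.
  The women's APC interval in the per-sex table is not reproducible from
  the stated formula with either the stratum or the pooled O (likely a
  digit transposition), so CI reproduction targets use the men's rows.
* The model-selection pipeline decides on the pooled (both-sex) E/O by
  default and records per-sex outcomes alongside.
* Projection horizon defaults to four 5-year periods with a 20-year
  default refit window (the last 20 observed years).
* Report CSVs round expected cases to integers at write time only; all
  internal arithmetic is unrounded.

## Known limitations

* The APC fitter requires a complete rectangle with positive
  person-years in every cell; ragged registries must be pre-trimmed.
* Cohort effects for unseen cohorts are extended at a constant level —
  long horizons lean heavily on the drift and attenuation choices.
* No uncertainty intervals on projections (point projections only), and
  no overdispersion variant of the Poisson model.
* The exposure model ignores fibre type, lung clearance and any
  sex-specific exposure split; its covariate inherits every assumption
  of the consumption reconstruction.
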