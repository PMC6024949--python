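# Methods

## Scope and pipeline

`aqburden` computes, for a panel of cities observed over several years,
the health burden attributable to ambient PM2.5 above a baseline
concentration and its monetary value, with uncertainty. The stages are
pure functions over validated tables: endpoint configuration → panel I/O
→ exposure–response → valuation → aggregation/reporting → Monte Carlo
propagation, with a synthetic-panel generator standing in for the
unpublished study data. Everything is deterministic given a seed; no
statistical fitting takes place, so there is no estimator object — the
functions and the `aqburden` CLI are the interface.

## Exposure–response model

Endpoint incidence follows the log-linear relative-risk form
`E_i(C) = E_0i exp(β_i (C − C_0))`, the standard Poisson-regression
shape for rare health events in air-pollution epidemiology. Attributable
cases are `HI_ij = P_j E_0i (exp(β_i (C − C_0)) − 1)`.

Numerical choices:

* **Baseline clamp.** `C < C_0` yields zero attributable cases and a
  `clamped` flag rather than negative "benefits"; the model quantifies
  excess burden above the guideline. The clamp is logged per row, never
  an error.
* **Overflow guard.** `|β (C − C_0)| ≤ 50` (module constant). β is
  per-µg/m³ and typically ≪ 0.1, so a violation almost always means the
  coefficient was supplied in the wrong units; the pipeline fails loudly
  naming the magnitude instead of returning `inf`.
* **Continuity.** Cases are kept as continuous floats internally;
  rounding to whole cases is a rendering concern.
* **Vectorization.** `impact_table` computes all (record × endpoint)
  cells with numpy and is tested cell-by-cell against the scalar
  `attributable_cases` path at 1e-9 relative tolerance.

Parameters (`AssessmentParams`): baseline concentration C₀ = 10 µg/m³
(WHO guideline); all defaults validated at construction.

## Valuation

Mortality is bounded from above by a value-of-statistical-life (VSL)
benefit transfer, `VSL_j = VSL_0 (Income_j / Income_0)^0.8` with
VSL₀ = 248,172 USD at Income₀ = 1,939 USD/yr, and from below by an
amended human-capital value: per-capita GDP discounted over t = 10
life-years lost, `GDP_j Σ_{y=1..t} ((1+a)/(1+r))^y` with growth a = 0.07
and discount rate r = 0.08. The multiplier is computed by direct
summation (and property-tested against the geometric closed form
`q(1−q^t)/(1−q)` to 1e-12 away from q = 1).

Morbidity uses cost of illness: a fixed per-case USD cost
(`per_case_fixed`) or a disability-weighted VSL fraction
(`vsl_fraction`; chronic bronchitis carries weight 0.055). Both rules
are bound-independent, so the two bound columns differ only through
mortality. Chronic bronchitis deliberately uses the *city VSL* in both
bounds rather than the human-capital value: the weighted-VSL approach is
how chronic-disease disability is monetized here, and it keeps morbidity
identical across bounds.

The income/GDP used for a death in year y is the record's own-year
value; no separate base-year convention is maintained.

## Endpoint taxonomy and double counting

The default set has four mortality endpoints (all-cause, cardiovascular,
respiratory, lung cancer) and four morbidity endpoints (cardiovascular
hospitalization, chronic bronchitis, acute bronchitis, asthma attack).
Cause-specific mortality overlaps with all-cause mortality, so totals
count only the all-cause endpoint, and the affected population is the
sum over the five non-overlapping endpoints (all-cause + the four
morbidity). Cause-specific results are still computed and reported per
endpoint. `validate_affected_partition` checks the canonical flag set
and returns a diagnostic rather than raising.

All-cause mortality is a distinct endpoint with its own coefficient, not
the sum of the cause-specific endpoints (their attributable cases do not
add up to the all-cause value, since each has its own β and E₀).
A cardiopulmonary-mortality endpoint is representable by the schema but
not in the default configuration, which mirrors the reported eight-row
taxonomy.

**Coefficient provenance.** β/E₀ pairs come from pooled epidemiological
meta-analysis in substantive studies; no canonical public table exists,
so the packaged defaults are *illustrative placeholders* chosen in the
ranges typical of the Chinese PM2.5 literature (e.g. all-cause mortality
β = 7e-4 per µg/m³ on a 6e-3 baseline). They make magnitudes realistic
but are not citable estimates; the config loader exists so users drop in
their own table.

## Synthetic panel generator

The generator emulates the study conditions: 190 cities, years
2014–2016, national mean concentrations 62/50/47 µg/m³, and 71% of
cities inside the 35–75 µg/m³ band in the final year.

* **Concentration marginal.** Log-normal — the simplest strictly
  positive right-skewed family able to hit a mean and a band-probability
  target simultaneously. The mean constraint is analytic
  (µ = ln m − σ²/2); the common log-sd is solved by Brent root-finding
  so the final-year band probability equals 0.71 to 1e-10 (verified in
  tests against numeric integration of the density). Infeasible
  (mean, band-probability) pairs raise a calibration error reporting the
  achievable maximum.
* **Persistence.** City j's standard-normal score in year y is
  `√ρ z_j + √(1−ρ) ε_jy` with ρ = 0.8, preserving each year's marginal
  while making polluted cities stay polluted (log-scale year-to-year
  correlation ≈ 0.8).
* **Socioeconomics.** Disposable income and per-capita GDP are
  log-normal with medians 3,500 and 7,500 USD and log-sds 0.35/0.45,
  coupled by a Gaussian copula at Spearman rank correlation 0.7 (the
  normal-score correlation uses the 2·sin(πρ/6) conversion); population
  is log-normal (median 4 million, log-sd 0.7), independent of income —
  values typical of Chinese prefecture-level cities in the period, which
  put total exposed population near one billion and total GDP near the
  right order of magnitude. Income and GDP grow 7%/yr nominally from the
  base-year draw; population is held fixed over the three years.

What the generator does **not** emulate: geography (no spatial
correlation or regional labels), within-year seasonality, station-level
sampling error, reporting gaps, or any income–pollution dependence.
Passing tests therefore demonstrate the pipeline's arithmetic and
calibration machinery, not agreement with any real city's burden — with
the illustrative coefficients the synthetic mortality share of total
losses (≈39–78% across bounds) is lower than the published ≈80–95%,
which is a property of the placeholder β/E₀ and cost levels, not of the
method.

## Aggregation and reporting conventions

* National totals are exact sums of city totals per endpoint
  (conservation tested at 1e-9 relative).
* `EC_total = EC_mortality + EC_morbidity` holds identically at every
  scope.
* The mean annual percent decline is the arithmetic mean of
  year-over-year percent declines, **truncated** (not rounded) to one
  decimal for reporting — the convention under which the published
  mortality series (278,444 → 238,622 → 216,164) yields exactly 11.8%.
* Money is computed in nominal USD and divided by 1e8 (hundred-million
  USD) only in rendered reports; ratios are computed from unrounded
  totals.
* City rankings sort by summed total loss descending with lexicographic
  city-id tie-breaks, making them invariant to input row order.
* Spatial outputs are tabular (per-city values and changes); no map
  rendering.

## Monte Carlo uncertainty

Uncertain inputs — concentration, β, and unit costs — are represented as
*multiplicative factors* with unit-median distributions, sampled
independently per draw (a point mass at 1 disables a quantity). Default
families: log-normal for concentration (positive, skewed), normal
truncated at 0 for β (pooled-estimate intervals are symmetric),
triangular for costs (bounded expert ranges). Truncation is applied by
resampling, so the retained law is the conditional one. Factors apply
uniformly across cities and endpoints; per-quantity correlation
structure is deliberately out of scope.

Per draw, the attributable-case and loss arithmetic is re-evaluated over
a flattened (record × endpoint) array restricted to the endpoints that
enter `EC_total`; the deterministic pipeline and this fast path agree to
1e-12 relative at degeneracy (different summation orders preclude a
bitwise contract). Cost factors touch VSL-based and cost-of-illness
values but never the human-capital value, whose input (per-capita GDP)
carries no modeled uncertainty; the lower bound still inherits
concentration and β uncertainty through the cases. Non-finite draw
outputs are rejected and counted; more than 1% rejections fails the run.

Summaries per bound: sample mean; percentile (2.5/97.5) 95% CI — robust
to the skew that normal-approximation intervals would miss; relative
half-width `(hi − lo)/(2·mean)`; and `prob_within_5pct`, the fraction of
draws within ±5% of the sample mean. The headline **uncertainty
percentage** is `100 (1 − prob_within_5pct)` — the probability mass
outside the ±5% acceptable-error band. The acceptable-error phrasing
admits more than one operationalization, so the CI half-width is always
reported alongside; both are monotone in the input spreads (tested on a
σ grid).

## Problem sizes and determinism

Defaults are desk-scale: the full 190-city panel evaluates in well under
a second, and test-suite Monte Carlo runs use 20-city panels with
2,000–20,000 draws (the 20,000-draw runs pin distributional oracles such
as the log-normal quantile half-width to within 10%). All randomness
flows from explicit `numpy.random.default_rng` seeds: identical config
and seed give byte-identical panel CSVs and report files (hash-checked
in tests).

## Known limitations

* Exposure is the whole resident population, static across the year; no
  age structure, so VSL-based totals would overstate age-adjusted losses.
* The log-linear form is not the integrated (GBD-style)
  exposure–response and tends to give lower attributable mortality at
  high concentrations.
* Unit costs and coefficients ship as illustrative configuration, so
  absolute synthetic magnitudes are demonstrations only.
* City annual means weight all months equally (simple average over
  available months, with a 9-of-12 completeness flag) and ignore
  station-to-city aggregation error.
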