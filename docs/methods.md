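# Methods

This note documents the models, numerical choices, and limitations of the
`heatrisk` pipeline in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The mortality model and the MMT

Daily all-cause deaths per province are treated as quasi-Poisson: a Poisson
log-likelihood score with variance `φ·μ`, the dispersion `φ` estimated from
Pearson residuals. The temperature term is a DLNM crossbasis over lags
0–`lag_max` (default 14 days):

* **Exposure dimension** — natural cubic spline, 4 df, internal knots at the
  25/50/75% quantiles of the observed temperature series, boundary knots at
  its range. The spline is the truncated-power "natural" form (linear beyond
  the boundary knots).
* **Lag dimension** — an intercept plus the three curvature functions of a
  natural cubic spline whose three internal knots are equally spaced on the
  log lag scale inside (0, lag_max), for a 4-dimensional lag basis and a
  16-column crossbasis. Dropping the linear lag term keeps the basis at four
  columns; the retained intercept + curvature space still represents
  smoothly decaying lag structures, and the cumulative (lag-summed) curve —
  the quantity all downstream stages consume — is insensitive to this choice.

Covariates: a global intercept, province fixed effects, a linear secular
trend per province (day index / 365.25), day-of-week indicators (Monday
reference), a holiday indicator, and a 4-df natural spline in mean relative
humidity. Day and night temperatures are fitted as two separate models
against the same death series. Provinces are fitted jointly; lagging never
crosses a province or season-window boundary, and the first `lag_max` rows of
each block are excluded from the likelihood.

Fitting is IRLS (statsmodels GLM, Poisson family, log link) with convergence
tolerance 1e-10 and up to 300 iterations; a machine-precision deviance
plateau is accepted as converged. Rank deficiency raises before fitting.

**MMT search.** The cumulative log-RR is evaluated on a 0.1 °C grid between
the 1st and 99th percentiles of the observed temperatures (sparse tails
produce boundary artefacts, a standard concern in MMT estimation); the
minimiser is the MMT, ties breaking toward the lower temperature, and a flat
curve is flagged with a warning. The model is fitted once with an arbitrary
reference; the curve is then re-centred at the located minimum so that
`RR(MMT) = 1` holds exactly by construction. Pointwise confidence bands come
from the delta method on the crossbasis coefficient covariance (scaled by the
estimated dispersion). The RR entering the attribution stage is the
cumulative RR at the 99th percentile of the temperature data.

## Raster operations

LST grids are scaled-Kelvin integers (×0.02, valid 7500–65535, fill 0);
decoding maps fill to missing and flags any other out-of-range value as
corrupt input. Zonal statistics use centre-of-pixel zone membership and
ignore missing pixels; a zone with no valid pixel on a day yields a missing
province-day maximum. Temporal maximum composites are per-pixel maxima over
valid observations only. Mosaicking copies valid pixels onto a fill canvas
and rejects conflicting overlaps. Zone areas are supplied per zone
(0.93 km pixels ⇒ 0.8649 km² each); projection handling is out of scope.

Missing province-day maxima are completed by multivariate imputation with
chained equations (statsmodels `MICEData`, predictive mean matching with 5
donors): the panel is pivoted wide (one column per province and phase, plus
seasonal sine/cosine and year covariates), cycled 10 times, and 5 imputations
are averaged. Observed values are never altered; a column less than half
observed, or missingness outside the temperature columns, is an error.

## Composite indices and the ensemble

Min–max normalisation is the single rescaling primitive; the hazard variant
anchors the floor at the MMT so sub-threshold pixels carry zero hazard.
Order of operations, applied identically for hazard and exposure: pixel-level
normalisation over city pixels → pixelwise day/night average (hazard only) →
city mean over valid pixels → re-normalisation of the city values to [0, 1].
Constant input normalises to all zeros with a warning rather than NaN, so a
degenerate indicator cannot poison an aggregation.

AHP weights are the principal right eigenvector of each reciprocal pairwise
matrix, normalised to sum 1; CI = (λ_max − n)/(n − 1), CR = CI/RI with
Saaty's random indices, CR ≡ 0 for 2×2 matrices. An expert is retained only
if every one of their matrices has CR ≤ 0.1 (the conventional threshold,
exposed as `cr_threshold`). Vulnerability per expert is
`w_S·S + w_C·(1−C)` — capacity inverted because it reduces vulnerability —
re-normalised across cities. Risk is the weighted additive aggregate
`RI = w_H·H + w_E·E + w_V·V`; the HHRI is the mean over retained experts with
a 95% CI of `mean ± t_{0.975,k−1}·SD/√k` (the CI method is a package choice;
bounds are reported unclipped and may extend past [0, 1] even though indices
themselves cannot). Categories are five equal bins with inclusive upper
limits (0.80 → "high", 0.81 → "very high").

## Attribution and validation

City mortality share M = (city population / province population) × province
mean daily deaths. Attributable deaths x = ((RR−1)/RR)·M per phase, averaged
between day and night; negative values (RR < 1) are retained and flagged, not
truncated. NDAH = x/A with A the city land area. Validation is the Pearson
correlation between per-city HHRI and NDAH with a two-sided t-test, dropping
and counting incomplete pairs.

## The synthetic generator

The generator emulates the statistical structure of the study inputs, not
their geography:

* **Temperature fields.** Per phase, a latent province-day series: base level
  set just below the true MMT (day 38.3 − 1.0 °C, night 24.3 − 0.4 °C), a
  half-sine within-season harmonic (amplitude 1.8/1.0 °C), province offsets
  (±1.2/±0.8 °C, warmest first), and national plus province-level daily
  anomalies (SD 1.6+1.0 / 1.0+0.7 °C). The pixel field subtracts a smooth
  north–south deficit gradient with one Gaussian urban hot core per province
  (deepest in the capital) and adds small pixel noise, then encodes to scaled
  Kelvin. Cloud missingness is i.i.d. Bernoulli per pixel-day
  (`cloud_prob`, default 0.08) plus rare province-wide overcast days
  (`overcast_prob`, default 0.05); the overcast events exist so that whole
  province-day maxima can genuinely go missing and the imputation stage has
  real work to do.
* **Mortality.** Province baselines assume a constant per-capita death rate:
  each province's expected deaths/day scale with its population (national
  mean 30 deaths/day), so the populous capital province carries most of the
  absolute mortality — the common driver that links population density to
  attributable-death density in the validation stage.
  Log-rate = log(province baseline) + kernel-weighted
  lagged V-shaped response for each phase (slopes +0.10/−0.04 log-RR per °C
  around the true MMTs; exponential-decay kernel over 15 lags summing to 1)
  + centred small covariate effects (RH +0.002/unit, weekend −2%,
  holiday +5%, trend +1%/year). The V-shape is piecewise linear precisely so
  the ground truth shares no basis with the spline estimator. Counts are
  negative binomial with size μ/(φ−1), giving exactly the quasi-Poisson
  variance φμ (Poisson at φ = 1). Lag padding at season starts holds the
  first in-window value; those rows are excluded from fitting anyway.
* **Indicators.** The capital is Manila-like: density 42,628 /km², low
  poverty, low greenness, high incomes; provincial cities draw correlated
  plausible values (poverty 0.15–0.55, incomes log-normal and decreasing in
  poverty, EVI 0.30–0.70). The density grid and table are consistent by
  construction.
* **Experts.** True component weights are the reported ensemble means
  (hazard/exposure/vulnerability 0.22/0.45/0.33; sensitivity/capacity
  0.44/0.56); indicator-level weights (0.30/0.25/0.45 and 0.25/0.35/0.40)
  are package choices, since no indicator-level table is public. Matrices
  are built as `w_i/w_j` around log-normally perturbed weights (hence
  perfectly consistent); a configurable subset (default 12 of 24) has its
  risk matrix multiplicatively degraded until CR exceeds the screening
  threshold, so screening retains exactly the other half.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: real geography and projections, spatial autocorrelation
of cloud cover, correlation between day and night temperature anomalies
(generated independently so each single-phase fit is unconfounded; real LSTs
correlate strongly), harvesting/mortality displacement, city-level mortality
processes beyond population-share apportionment, and calibrated demographics.

## Problem sizes and defaults

Default desk scale: 6 provinces × 3 cities on a 40×60 grid, hot dry seasons
(March–May) 2006–2011 ⇒ 552 days × 6 provinces = 3312 panel rows, 24 experts.
A full pipeline run takes ~20 s on one CPU; the multi-seed recovery and
null-calibration experiments in the test suite use 20 and 200 replicates
respectively. Determinism: every stochastic component draws from a named
substream seeded from the single configuration seed, so identical
configurations yield byte-identical rasters and identical reports.

## Known limitations

* The across-city re-normalisation makes every index relative to the city set
  being analysed; indices are not comparable across runs with different city
  rosters.
* With very few retained experts the t-based CI is wide and, below two, the
  CI is unavailable by construction.
* The quasi-Poisson Wald test of the crossbasis block is asymptotic; its
  type-I error is verified by simulation at the default scale only.
* PMM-based imputation cannot extrapolate beyond observed donor values; under
  heavy, systematic missingness its error approaches that of a mean fill.
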