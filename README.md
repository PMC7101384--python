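# heatrisk

City-level **heat health risk assessment** from remotely sensed surface
temperature and social-ecological indicators, built around the IPCC AR5 risk
framing: *risk = f(hazard, exposure, vulnerability)*.

The package is aimed at environmental epidemiologists and climate-adaptation
analysts who want a tested, reusable implementation of this assessment chain:

1. **Minimum mortality temperature (MMT).** Daily province-level all-cause
   death counts `Y_{t,c}` are modelled with a quasi-Poisson distributed-lag
   non-linear model (DLNM):

   ```
   E(log Y_{t,c}) = α + cbTemp_{t,c,v} + Σ_j β_j cov_j + ns(RH_ave, 4)
   ```

   where `cbTemp` is a crossbasis — the tensor product of a natural cubic
   spline in temperature (4 df) and a lag basis over 0–14 days (intercept plus
   three natural-spline terms with knots equally spaced on the log lag
   scale) — and the covariates are province intercepts, per-province secular
   trends, day of week, holidays, and a 4-df spline in relative humidity.
   The cumulative relative-risk curve `RR(T)` is re-centred at its minimum,
   the MMT, so `RR(MMT) = 1`.

2. **Hazard / exposure / vulnerability indices.** Day and night LST maximum
   composites are min–max normalised with the MMTs as floors (LST ≤ MMT ⇒
   hazard 0), averaged and aggregated per city; exposure comes from
   population density; vulnerability combines sensitivity (young/old
   population, poverty) with inverted coping capacity (greenness, incomes).

3. **Risk ensemble.** Per expert, `RI_i = Σ_j x_ij w_j` with AHP
   (principal-eigenvector) weights from pairwise-comparison matrices;
   experts with any consistency ratio above 0.1 are screened out. The heat
   health risk index (HHRI) is the ensemble mean with a t-based 95% CI and a
   five-level category label (upper limits inclusive).

4. **Validation.** Heat-attributable deaths per km² (NDAH) via the
   attributable fraction `(RR−1)/RR` at the 99th-percentile temperature,
   correlated with the HHRI (Pearson's r).

Because the underlying vital statistics, satellite archives, and expert
questionnaires are not redistributable, the package ships a fully specified
**synthetic data generator** (`heatrisk.simulate`) whose ground truth (MMTs,
weights, latent temperatures) is known exactly, so every stage is testable as
a parameter-recovery problem.

## Worked example

```python
from heatrisk import CrossbasisSpec, fit_phase
from heatrisk.simulate import SimConfig, gen_daily_panel

config = SimConfig(seed=0)            # 6 provinces × 552 hot-dry-season days
panel, truth = gen_daily_panel(config)
day = fit_phase(panel, CrossbasisSpec(), "day")
night = fit_phase(panel, CrossbasisSpec(), "night")
print(f"day   MMT {day.mmt:.1f} °C (truth {truth.mmt_day}),  RR at p99 {day.rr_p99:.2f}")
print(f"night MMT {night.mmt:.1f} °C (truth {truth.mmt_night}),  RR at p99 {night.rr_p99:.2f}")
print(f"quasi-Poisson dispersion: {day.fit.dispersion:.2f}")
```

prints

```
day   MMT 38.2 °C (truth 38.3),  RR at p99 1.77
night MMT 23.8 °C (truth 24.3),  RR at p99 1.75
quasi-Poisson dispersion: 1.61
```

i.e. the fitted RR curves bottom out within a few tenths of a degree of the
generating optima (a single seed can miss by a degree or two; the median
absolute error over 20 seeds is well under 1 °C), mortality risk at the
hottest 1% of days is ~1.8× the optimum, and overdispersion near the
requested 1.5 is recovered.

The same thing end to end, including rasters, indices and validation:

```bash
heatrisk all --seed 42 --out run/
```

which reports (see `run/report.json` for the full machine-readable version)
MMTs of 38.8/21.7 °C, 12 of 24 experts retained, ensemble component weights
0.22/0.46/0.32 (hazard/exposure/vulnerability) and 0.44/0.56
(sensitivity/capacity), the dense hot capital city on top of the risk ranking
(HHRI 0.69, 95% CI 0.66–0.72, "high"), and a positive HHRI–NDAH validation
correlation (r = 0.67, p = 0.002, 18 cities).

Stages can also be run individually: `heatrisk simulate`, `fit-mmt`,
`composite`, `risk`, `validate`, sharing artifacts through the run directory.

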