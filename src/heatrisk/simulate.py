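"""Synthetic inputs with known ground truth for the whole pipeline.

Everything the real study reads from satellite archives, census tables,
vital statistics, and expert questionnaires is emulated here with a known
generating process, so every downstream stage can be tested for parameter
recovery:

* day/night LST stacks over a gridded toy country (smooth north–south
  gradient, one urban "hot core" per province, cloud-driven missingness),
  encoded exactly like the real product (scaled Kelvin, fill 0);
* daily province mortality counts whose log-rate follows a known V-shaped
  lagged temperature response with minimum at the true MMT, drawn with
  quasi-Poisson overdispersion via a matching negative binomial;
* a city indicator table (age structure, poverty, greenness, incomes,
  population density) with stated polarities, plus a density grid;
* reciprocal expert pairwise matrices built around perturbed true weights,
  with a configurable subset made deliberately inconsistent to exercise
  consistency screening.

Only statistical structure is emulated — no real geography or projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import calendar
import numpy as np
import pandas as pd

from . import composite
from .composite import (CAPACITY_INDICATORS, PairwiseMatrix,
                        SENSITIVITY_INDICATORS, consistent_matrix)
from .raster import (FILL_VALUE, RasterStack, ZoneMap, encode_lst,
                     zonal_stat_stack)

# independent substreams per generated artifact, keyed off the config seed
_STREAMS = {"field_day": 0, "field_night": 1, "cloud_day": 2, "cloud_night": 3,
            "mortality": 4, "rh": 5, "indicators": 6, "experts": 7, "density": 8,
            "pix_day": 9, "pix_night": 10}

#: True component weights: the risk and vulnerability groups use the study's
#: reported ensemble means; indicator-level groups are plausible inventions.
TRUE_WEIGHTS = {
    "risk": np.array([0.22, 0.45, 0.33]),          # hazard, exposure, vulnerability
    "vulnerability": np.array([0.44, 0.56]),       # sensitivity, capacity
    "sensitivity": np.array([0.30, 0.25, 0.45]),   # young, old, poverty
    "capacity": np.array([0.25, 0.35, 0.40]),      # EVI, city income, per-capita
}

#: Fixed-date public holidays inside the hot dry season (Day of Valor, Labor Day).
HOLIDAYS = ((4, 9), (5, 1))


def _default_lag_kernel(lag_max: int = 14) -> np.ndarray:
    w = np.exp(-np.arange(lag_max + 1) / 3.0)
    return w / w.sum()


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the real study's scale where it is stated (6-year
    hot-dry-season mortality window, MMTs 38.3/24.3 °C, 24 experts of whom 12
    are inconsistent) at a desk-scale grid.
    """

    n_provinces: int = 6
    cities_per_province: int = 3
    grid_shape: tuple = (40, 60)
    years: tuple = (2006, 2007, 2008, 2009, 2010, 2011)
    season_months: tuple = (3, 4, 5)
    true_mmt_day: float = 38.3
    true_mmt_night: float = 24.3
    heat_slope: float = 0.10   # log-RR per °C above the MMT
    cold_slope: float = 0.04   # log-RR per °C below the MMT
    lag_kernel: np.ndarray = None
    baseline_mortality: float = 30.0
    dispersion: float = 1.5
    cloud_prob: float = 0.08
    overcast_prob: float = 0.05  # province-wide cloud day (whole zone masked)
    n_experts: int = 24
    n_inconsistent: int = 12
    expert_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_kernel is None:
            self.lag_kernel = _default_lag_kernel()
        self.lag_kernel = np.asarray(self.lag_kernel, dtype=float)
        if self.n_provinces < 1 or self.cities_per_province < 1:
            raise ValueError("need at least one province and city")
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise ValueError("grid_shape must be positive")
        if not self.years:
            raise ValueError("year list must be non-empty")
        if (self.lag_kernel < 0).any() or abs(self.lag_kernel.sum() - 1.0) > 1e-9:
            raise ValueError("lag_kernel must be non-negative and sum to 1")
        if not (0 <= self.cloud_prob < 1) or not (0 <= self.overcast_prob < 1):
            raise ValueError("cloud probabilities must lie in [0, 1)")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")
        if self.n_inconsistent > self.n_experts:
            raise ValueError("cannot force more inconsistent experts than experts")

    @property
    def n_cities(self) -> int:
        return self.n_provinces * self.cities_per_province

    @property
    def capital_city(self) -> int:
        """The engineered dense hot capital: middle city of province 0."""
        return self.cities_per_province // 2

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), _STREAMS[stream]])
        )


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    mmt_day: float = np.nan
    mmt_night: float = np.nan
    weights: dict = field(default_factory=dict)
    latent_day: pd.DataFrame = None    # dates × provinces, °C
    latent_night: pd.DataFrame = None
    indicators: pd.DataFrame = None
    density_grid: np.ndarray = None


def season_dates(config: SimConfig) -> pd.DatetimeIndex:
    months = set(config.season_months)
    days = []
    for y in sorted(config.years):
        for m in sorted(months):
            days += [Date(y, m, d) for d in range(1, calendar.monthrange(y, m)[1] + 1)]
    return pd.DatetimeIndex(days)


def make_zone_map(config: SimConfig) -> ZoneMap:
    """Provinces are vertical strips; cities are row bands inside each strip,
    separated by non-city province margin."""
    rows, cols = config.grid_shape
    P, cpp = config.n_provinces, config.cities_per_province
    province = np.zeros((rows, cols), dtype=int)
    edges = np.linspace(0, cols, P + 1).astype(int)
    for p in range(P):
        province[:, edges[p]:edges[p + 1]] = p
    city = np.full((rows, cols), -1, dtype=int)
    band = np.linspace(0, rows, cpp + 1).astype(int)
    mapping = {}
    for p in range(P):
        for c in range(cpp):
            cid = p * cpp + c
            r0, r1 = band[c], band[c + 1]
            c0, c1 = edges[p], edges[p + 1]
            # one-pixel margin keeps some province area outside any city
            city[r0 + 1:r1, c0 + 1:c1] = cid
            mapping[cid] = p
    return ZoneMap(province, city, mapping)


# ---------------------------------------------------------------------------
# LST fields
# ---------------------------------------------------------------------------

_PHASE_PARAMS = {
    # base offset from MMT, harmonic amplitude, province spread, national and
    # province daily-anomaly SDs, pixel noise SD
    "day": dict(base=-1.0, harmonic=1.8, spread=1.2, nat_sd=1.6, prov_sd=1.0,
                pix_sd=0.3),
    "night": dict(base=-0.4, harmonic=1.0, spread=0.8, nat_sd=1.0, prov_sd=0.7,
                  pix_sd=0.2),
}


def _province_offsets(config: SimConfig, spread: float) -> np.ndarray:
    # province 0 (the capital's) is the warmest
    return np.linspace(spread, -spread, config.n_provinces)


def _day_of_season(dates: pd.DatetimeIndex, config: SimConfig) -> np.ndarray:
    months = sorted(set(config.season_months))
    out = np.empty(len(dates), dtype=float)
    for y in sorted(set(dates.year)):
        sel = dates.year == y
        out[sel] = np.arange(int(sel.sum()))
    return out


def latent_series(config: SimConfig, phase: str) -> pd.DataFrame:
    """Daily province-level latent temperature (°C): dates × provinces."""
    p = _PHASE_PARAMS[phase]
    mmt = config.true_mmt_day if phase == "day" else config.true_mmt_night
    dates = season_dates(config)
    rng = config.rng(f"field_{phase}")
    dos = _day_of_season(dates, config)
    n_season = max(dos.max(), 1.0)
    harmonic = p["harmonic"] * np.sin(np.pi * dos / n_season)
    nat = rng.normal(0.0, p["nat_sd"], size=len(dates))
    prov = rng.normal(0.0, p["prov_sd"], size=(len(dates), config.n_provinces))
    offsets = _province_offsets(config, p["spread"])
    vals = (mmt + p["base"] + harmonic[:, None] + nat[:, None]
            + offsets[None, :] + prov)
    return pd.DataFrame(vals, index=dates, columns=range(config.n_provinces))


def _deficit_map(config: SimConfig, zones: ZoneMap) -> np.ndarray:
    """Per-pixel temperature deficit (°C >= 0): a smooth north–south gradient
    plus an urban hot core per province where the deficit vanishes.  The
    capital city hosts the deepest (hottest) core."""
    rows, cols = config.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    gradient = 1.5 * rr / max(rows - 1, 1)
    deficit = gradient + 2.0
    sigma = max(min(rows, cols) / 10.0, 2.0)
    for p in range(config.n_provinces):
        cid = p * config.cities_per_province + config.capital_city
        mask = zones.city_labels == cid
        if not mask.any():
            continue
        r0, c0 = (np.mean(np.nonzero(mask)[i]) for i in (0, 1))
        amp = 2.0 + gradient[int(r0), int(c0)] + (0.8 if p == 0 else 0.0)
        deficit -= amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return np.clip(deficit, 0.0, None)


def _phase_field(config: SimConfig, phase: str, zones: ZoneMap):
    """Unmasked per-pixel °C field for every season day of one phase."""
    p = _PHASE_PARAMS[phase]
    latent = latent_series(config, phase)
    deficit = _deficit_map(config, zones)
    rng = config.rng(f"pix_{phase}")
    prov_labels = zones.province_labels
    field_ = latent.to_numpy()[:, prov_labels] - deficit[None, :, :]
    field_ += rng.normal(0.0, p["pix_sd"], size=field_.shape)
    return latent.index, field_, latent


def gen_lst_stack(config: SimConfig, phase: str, zones: ZoneMap = None) -> RasterStack:
    """One encoded scene per season day with Bernoulli cloud missingness.

    Missing pixels carry the fill value 0; with ``cloud_prob = 0`` and
    ``overcast_prob = 0`` every pixel is valid.
    """
    if phase not in ("day", "night"):
        raise ValueError("phase must be 'day' or 'night'")
    zones = zones or make_zone_map(config)
    dates, field_, _ = _phase_field(config, phase, zones)
    encoded = encode_lst(field_)
    rng = config.rng(f"cloud_{phase}")
    if config.cloud_prob > 0:
        mask = rng.random(encoded.shape) < config.cloud_prob
        encoded[mask] = FILL_VALUE
    if config.overcast_prob > 0:
        overcast = rng.random((len(dates), config.n_provinces)) < config.overcast_prob
        prov_labels = zones.province_labels
        for p in range(config.n_provinces):
            zone_mask = prov_labels == p
            for d in np.flatnonzero(overcast[:, p]):
                encoded[d][zone_mask] = FILL_VALUE
    return RasterStack(encoded, [d.date() for d in dates], phase)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def _v_response(temps: np.ndarray, mmt: float, heat: float, cold: float) -> np.ndarray:
    """Piecewise-linear V-shaped log-RR with its minimum (0) at the MMT."""
    return heat * np.clip(temps - mmt, 0, None) + cold * np.clip(mmt - temps, 0, None)


def _lagged_effect(f: np.ndarray, kernel: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """Kernel-weighted lagged sum, edge-held at each block start."""
    out = np.empty_like(f)
    change = np.flatnonzero(np.r_[True, blocks[1:] != blocks[:-1]])
    bounds = np.r_[change, len(f)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = f[s:e]
        idx = np.arange(len(seg))
        acc = np.zeros(len(seg))
        for lag, w in enumerate(kernel):
            acc += w * seg[np.clip(idx - lag, 0, None)]
        out[s:e] = acc
    return out


def draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with quasi-Poisson variance φμ: Poisson at φ = 1, otherwise a
    negative binomial with size r = μ/(φ−1) so Var = μ + μ²/r = φμ."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 1.0:
        return rng.poisson(mu)
    r = mu / (dispersion - 1.0)
    return rng.negative_binomial(r, r / (r + mu))


def _province_baselines(config: SimConfig, zones: ZoneMap) -> np.ndarray:
    """Expected deaths/day per province: constant per-capita mortality, so
    province baselines scale with province population (the national mean
    stays at ``baseline_mortality``).  Populous hot cities therefore carry
    genuinely higher absolute mortality, the common driver the validation
    stage relies on."""
    table, _ = gen_indicator_table(config, zones)
    pop = table.groupby("province")["population"].sum().sort_index().to_numpy()
    return config.baseline_mortality * pop / pop.mean()


def _assemble_panel(config: SimConfig, obs_day: pd.DataFrame,
                    obs_night: pd.DataFrame, lat_day: pd.DataFrame,
                    lat_night: pd.DataFrame, baselines: np.ndarray):
    """Build the daily panel; counts are generated from the *latent* (cloud-
    free) temperatures so that ground truth is exact."""
    dates = lat_day.index
    rng = config.rng("mortality")
    rng_rh = config.rng("rh")
    dos = _day_of_season(dates, config)
    n_season = max(dos.max(), 1.0)
    holiday = np.array([(d.month, d.day) in HOLIDAYS for d in dates], dtype=float)
    dow = dates.dayofweek.to_numpy()
    # covariate effects are centered so the marginal mean stays at baseline
    weekend = (dow >= 5).astype(float)
    weekend_c = weekend - weekend.mean()
    holiday_c = holiday - holiday.mean()
    year_c = dates.year.to_numpy() - np.mean(config.years)

    frames = []
    for p in range(config.n_provinces):
        rh = np.clip(65 + 8 * np.sin(2 * np.pi * dos / n_season)
                     + rng_rh.normal(0, 5, len(dates)), 30, 95)
        blocks = dates.year.to_numpy()
        f_day = _v_response(lat_day[p].to_numpy(), config.true_mmt_day,
                            config.heat_slope, config.cold_slope)
        f_night = _v_response(lat_night[p].to_numpy(), config.true_mmt_night,
                              config.heat_slope, config.cold_slope)
        log_mu = (np.log(baselines[p])
                  + _lagged_effect(f_day, config.lag_kernel, blocks)
                  + _lagged_effect(f_night, config.lag_kernel, blocks)
                  + 0.002 * (rh - 65.0) - 0.02 * weekend_c + 0.05 * holiday_c
                  + 0.01 * year_c)
        deaths = draw_counts(np.exp(log_mu), config.dispersion, rng)
        frames.append(pd.DataFrame({
            "province": p, "date": dates, "deaths": deaths,
            "temp_day": obs_day[p].to_numpy(), "temp_night": obs_night[p].to_numpy(),
            "rh": rh, "holiday": holiday.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_mortality_panel(config: SimConfig, lst_day: RasterStack,
                        lst_night: RasterStack, zones: ZoneMap):
    """Daily panel whose temperatures are the observed (cloud-affected)
    province maxima of the stacks, with counts driven by the cloud-free maxima.

    Returns ``(panel, truth)``; the truth carries the latent per-province
    series actually used in generation.
    """
    if [d for d in lst_day.dates] != [d for d in lst_night.dates]:
        raise ValueError("day and night stacks must cover identical dates")
    obs_day = zonal_stat_stack(lst_day, zones, "max", "province")
    obs_night = zonal_stat_stack(lst_night, zones, "max", "province")
    # cloud-free fields regenerated from the same substreams the stacks used
    prov = zones.province_labels
    truth_frames = {}
    for phase in ("day", "night"):
        dates, field_, _ = _phase_field(config, phase, zones)
        maxima = np.stack([field_[:, prov == p].max(axis=1)
                           for p in range(config.n_provinces)], axis=1)
        truth_frames[phase] = pd.DataFrame(maxima, index=dates,
                                           columns=range(config.n_provinces))
    panel = _assemble_panel(config, obs_day, obs_night,
                            truth_frames["day"], truth_frames["night"],
                            _province_baselines(config, zones))
    truth = GroundTruth(mmt_day=config.true_mmt_day, mmt_night=config.true_mmt_night,
                        weights=dict(TRUE_WEIGHTS), latent_day=truth_frames["day"],
                        latent_night=truth_frames["night"])
    return panel, truth


def gen_daily_panel(config: SimConfig):
    """Raster-free panel: temperatures are the latent province series itself.

    The statistically equivalent fast path for estimator studies that do not
    exercise the raster stages (no cloud gaps, no encoding quantisation).
    """
    lat_day = latent_series(config, "day")
    lat_night = latent_series(config, "night")
    baselines = _province_baselines(config, make_zone_map(config))
    panel = _assemble_panel(config, lat_day, lat_night, lat_day, lat_night,
                            baselines)
    truth = GroundTruth(mmt_day=config.true_mmt_day, mmt_night=config.true_mmt_night,
                        weights=dict(TRUE_WEIGHTS), latent_day=lat_day,
                        latent_night=lat_night)
    return panel, truth


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

#: Manila-like population density for the engineered capital (people/km²).
CAPITAL_DENSITY = 42628.0


def gen_indicator_table(config: SimConfig, zones: ZoneMap = None):
    """Per-city social-ecological indicators plus a consistent density grid.

    The capital is dense, low-poverty, low-greenness, high-income; provincial
    cities are sparser, poorer, greener, with correlated incomes.  Table
    densities are the city means of the generated grid, so grid and table are
    consistent by construction.
    """
    zones = zones or make_zone_map(config)
    rng = config.rng("indicators")
    rng_d = config.rng("density")
    n = config.n_cities
    capital = config.capital_city  # city id within province 0
    is_capital = np.zeros(n, dtype=bool)
    is_capital[capital] = True
    metro = np.array([zones.city_to_province[c] == 0 for c in range(n)])

    poverty = np.where(metro, rng.uniform(0.03, 0.15, n), rng.uniform(0.15, 0.55, n))
    young = np.clip(0.25 + 0.20 * poverty + rng.normal(0, 0.02, n), 0.0, 1.0)
    old = np.clip(0.035 + 0.03 * rng.random(n) + 0.02 * poverty, 0.0, 1.0)
    per_capita_income = np.exp(10.5 - 1.2 * poverty + rng.normal(0, 0.15, n))
    mean_evi = np.clip(np.where(is_capital, rng.uniform(0.12, 0.22, n),
                                rng.uniform(0.30, 0.70, n)), 0.0, 1.0)

    target_density = np.exp(rng.normal(7.2, 0.9, n))
    target_density[capital] = CAPITAL_DENSITY
    grid = np.exp(rng_d.normal(np.log(50.0), 0.3, zones.shape))
    for cid in range(n):
        mask = zones.city_labels == cid
        grid[mask] = target_density[cid] * np.exp(rng_d.normal(0, 0.05, mask.sum()))

    rows = []
    for cid in range(n):
        mask = zones.city_labels == cid
        area = zones.area_km2(cid)
        density = float(grid[mask].mean())
        rows.append({
            "city": cid, "province": zones.city_to_province[cid],
            "young_prop": young[cid], "old_prop": old[cid],
            "poverty_incidence": poverty[cid], "mean_evi": mean_evi[cid],
            "per_capita_income": per_capita_income[cid],
            "population_density": density, "area_km2": area,
            "population": density * area,
        })
    table = pd.DataFrame(rows)
    table["city_net_income"] = (table["per_capita_income"] * table["population"]
                                * 0.08)
    truth = GroundTruth(weights=dict(TRUE_WEIGHTS), indicators=table.copy(),
                        density_grid=grid)
    return table, truth


# ---------------------------------------------------------------------------
# expert matrices
# ---------------------------------------------------------------------------

_GROUP_ITEMS = {
    "risk": composite.RISK_COMPONENTS,
    "vulnerability": composite.VULN_COMPONENTS,
    "sensitivity": SENSITIVITY_INDICATORS,
    "capacity": CAPACITY_INDICATORS,
}


def _make_inconsistent(pm: PairwiseMatrix, rng: np.random.Generator,
                       cr_threshold: float = 0.1) -> PairwiseMatrix:
    """Multiplicatively perturb the upper triangle until CR exceeds threshold."""
    n = len(pm.items)
    scale = 0.4
    for _ in range(60):
        A = pm.matrix.copy()
        for i in range(n):
            for j in range(i + 1, n):
                A[i, j] *= np.exp(rng.normal(0.0, scale))
                A[j, i] = 1.0 / A[i, j]
        cand = PairwiseMatrix(pm.items, A)
        _, cr = composite.ahp_weights(cand)
        if cr > cr_threshold * 1.2:
            return cand
        scale *= 1.4
    raise RuntimeError("failed to construct an inconsistent matrix")


def gen_expert_matrices(config: SimConfig):
    """One set of reciprocal pairwise matrices per expert.

    Matrices are built as w_i/w_j around log-normally perturbed true weights
    (hence perfectly consistent, CR = 0); the first ``n_inconsistent``
    experts get their 3×3 risk matrix deliberately degraded past the CR
    screening threshold.  ``expert_noise = 0`` reproduces the true weights
    exactly.
    """
    if config.n_experts < 1:
        raise ValueError("need at least one expert")
    rng = config.rng("experts")
    experts = []
    for e in range(config.n_experts):
        matrices = {}
        for group, items in _GROUP_ITEMS.items():
            w = TRUE_WEIGHTS[group] * np.exp(
                rng.normal(0.0, config.expert_noise, len(items)))
            matrices[group] = consistent_matrix(items, w / w.sum())
        if e < config.n_inconsistent:
            matrices["risk"] = _make_inconsistent(matrices["risk"], rng)
        experts.append(matrices)
    truth = GroundTruth(weights=dict(TRUE_WEIGHTS))
    return experts, truth
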