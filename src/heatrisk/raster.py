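"""Gridded land-surface-temperature handling.

Scenes carry LST as scaled-Kelvin integers (scale factor 0.02, valid range
7500–65535, fill value 0 for cloud-contaminated pixels), the encoding used by
daily satellite LST products.  This module decodes them to °C, counts expected
layers for a study window, mosaics scenes, computes zonal statistics and
per-pixel temporal maximum composites, and fills missing province-day maxima
by multivariate imputation with chained equations.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

SCALE = 0.02
KELVIN_OFFSET = 273.15
FILL_VALUE = 0
VALID_MIN = 7500
VALID_MAX = 65535

#: MODIS-like pixel edge is ~0.93 km, so one pixel covers ~0.865 km^2.
PIXEL_AREA_KM2 = 0.93 * 0.93


class CorruptSceneError(ValueError):
    """Raw values outside the valid scaled-Kelvin range and not fill."""


@dataclass
class RasterScene:
    """One day's gridded LST in encoded (scaled Kelvin) form."""

    values: np.ndarray  # 2D integer grid
    date: Date
    phase: str  # "day" or "night"
    scene_id: str = "scene-0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("scene grid must be 2D and non-empty")
        if self.phase not in ("day", "night"):
            raise ValueError(f"phase must be 'day' or 'night', got {self.phase!r}")


@dataclass
class RasterStack:
    """A stack of same-shaped scenes (one per day) for one diurnal phase."""

    values: np.ndarray  # (n_days, rows, cols) integer
    dates: list
    phase: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("stack must be 3D (days, rows, cols)")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("one date per layer required")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self):
        return self.values.shape[1:]

    def scene(self, i: int) -> RasterScene:
        return RasterScene(self.values[i], self.dates[i], self.phase, f"scene-{i}")


@dataclass
class ZoneMap:
    """Pixel-to-zone assignment at province and city level.

    A pixel belongs to the zone covering its centre.  City zones nest inside
    provinces; pixels outside any city carry label -1 in ``city_labels``.
    Areas are supplied per zone (projection handling is out of scope).
    """

    province_labels: np.ndarray
    city_labels: np.ndarray
    city_to_province: dict
    pixel_area_km2: float = PIXEL_AREA_KM2

    def __post_init__(self) -> None:
        self.province_labels = np.asarray(self.province_labels)
        self.city_labels = np.asarray(self.city_labels)
        if self.province_labels.shape != self.city_labels.shape:
            raise ValueError("province and city label grids must share shape")
        # nesting invariant: each city's pixels sit inside one province
        for cid in self.city_ids():
            provs = np.unique(self.province_labels[self.city_labels == cid])
            if len(provs) != 1 or provs[0] != self.city_to_province[cid]:
                raise ValueError(f"city {cid} not nested in exactly one province")

    @property
    def shape(self):
        return self.province_labels.shape

    def province_ids(self):
        return sorted(int(p) for p in np.unique(self.province_labels))

    def city_ids(self):
        labs = np.unique(self.city_labels)
        return sorted(int(c) for c in labs[labs >= 0])

    def labels(self, level: str) -> np.ndarray:
        if level == "province":
            return self.province_labels
        if level == "city":
            return self.city_labels
        raise ValueError(f"unknown zone level {level!r}")

    def area_km2(self, zone: int, level: str = "city") -> float:
        n = int((self.labels(level) == zone).sum())
        if n == 0:
            raise KeyError(f"{level} zone {zone} absent from map")
        return n * self.pixel_area_km2


def decode_lst(values) -> np.ndarray:
    """Decode scaled-Kelvin integers to °C with NaN at fill pixels.

    T(°C) = raw × 0.02 − 273.15 at valid pixels.  Raw values that are neither
    fill (0) nor within [7500, 65535] indicate corrupt input and raise
    :class:`CorruptSceneError`.
    """
    raw = values.values if isinstance(values, RasterScene) else np.asarray(values)
    bad = (raw != FILL_VALUE) & ((raw < VALID_MIN) | (raw > VALID_MAX))
    if bad.any():
        raise CorruptSceneError(
            f"{int(bad.sum())} raw values outside [{VALID_MIN}, {VALID_MAX}] and != {FILL_VALUE}"
        )
    out = raw.astype(float) * SCALE - KELVIN_OFFSET
    out[raw == FILL_VALUE] = np.nan
    return out


def encode_lst(temps_c: np.ndarray) -> np.ndarray:
    """Encode °C to scaled-Kelvin uint16; NaN becomes the fill value 0."""
    t = np.asarray(temps_c, dtype=float)
    raw = np.where(np.isnan(t), FILL_VALUE, np.round((t + KELVIN_OFFSET) / SCALE))
    if ((raw != FILL_VALUE) & ((raw < VALID_MIN) | (raw > VALID_MAX))).any():
        raise ValueError("temperature outside the encodable valid range")
    return raw.astype(np.uint16)


def count_expected_layers(years, months, phases: int = 2, scenes: int = 1) -> int:
    """Number of raster layers for a multi-year seasonal window.

    (sum of calendar days in the given months across the given years)
    × diurnal phases × scenes tiling the study area.
    """
    years = sorted(set(int(y) for y in years))
    months = sorted(set(int(m) for m in months))
    if not years or not months:
        raise ValueError("years and months must be non-empty")
    if any(m < 1 or m > 12 for m in months):
        raise ValueError("months must lie in 1..12")
    if phases < 1 or scenes < 1:
        raise ValueError("phases and scenes must be positive")
    days = sum(calendar.monthrange(y, m)[1] for y in years for m in months)
    return days * phases * scenes


def mosaic(scenes, placements, shape=None) -> RasterScene:
    """Mosaic same-date, same-phase scenes onto one canvas.

    ``placements`` gives the (row, col) offset of each scene's upper-left
    corner.  Valid pixels are copied; gaps stay fill.  Overlapping placements
    are allowed only where the overlapping valid values agree.
    """
    if not scenes:
        raise ValueError("no scenes to mosaic")
    if len(placements) != len(scenes):
        raise ValueError("one placement per scene required")
    d0, p0 = scenes[0].date, scenes[0].phase
    if any(s.date != d0 or s.phase != p0 for s in scenes):
        raise ValueError("scenes must share date and phase")
    if shape is None:
        shape = (
            max(r + s.values.shape[0] for s, (r, c) in zip(scenes, placements)),
            max(c + s.values.shape[1] for s, (r, c) in zip(scenes, placements)),
        )
    canvas = np.full(shape, FILL_VALUE, dtype=scenes[0].values.dtype)
    for s, (r, c) in zip(scenes, placements):
        h, w = s.values.shape
        window = canvas[r : r + h, c : c + w]
        if window.shape != (h, w):
            raise ValueError("placement extends beyond the canvas")
        incoming = s.values
        clash = (window != FILL_VALUE) & (incoming != FILL_VALUE) & (window != incoming)
        if clash.any():
            raise ValueError("overlapping placements with conflicting valid values")
        np.copyto(window, incoming, where=incoming != FILL_VALUE)
    return RasterScene(canvas, d0, p0, "mosaic")


def zonal_stat(grid, zones: ZoneMap, stat: str = "max", level: str = "province",
               zone_ids=None) -> pd.Series:
    """Per-zone statistic over valid (non-NaN) pixels of a decoded °C grid.

    A zone whose pixels are all missing gets NaN.  Requesting a zone id that
    is absent from the map raises ``KeyError``.
    """
    grid = np.asarray(grid, dtype=float)
    labels = zones.labels(level)
    if grid.shape != labels.shape:
        raise ValueError("grid and zone map shapes differ")
    if stat not in ("max", "mean"):
        raise ValueError(f"unsupported statistic {stat!r}")
    present = zones.province_ids() if level == "province" else zones.city_ids()
    if zone_ids is None:
        zone_ids = present
    else:
        missing = [z for z in zone_ids if z not in present]
        if missing:
            raise KeyError(f"zone ids absent from map: {missing}")
    func = np.nanmax if stat == "max" else np.nanmean
    out = {}
    for z in zone_ids:
        vals = grid[labels == z]
        vals = vals[np.isfinite(vals)]
        out[z] = func(vals) if vals.size else np.nan
    return pd.Series(out, name=stat)


def zonal_stat_stack(stack: RasterStack, zones: ZoneMap, stat: str = "max",
                     level: str = "province") -> pd.DataFrame:
    """Vectorised per-day zonal statistic for a whole stack (dates × zones)."""
    decoded = decode_lst(stack.values)  # (n, R, C)
    labels = zones.labels(level)
    ids = zones.province_ids() if level == "province" else zones.city_ids()
    func = np.nanmax if stat == "max" else np.nanmean
    cols = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        for z in ids:
            cols[z] = func(decoded[:, labels == z], axis=1)
    return pd.DataFrame(cols, index=pd.DatetimeIndex(stack.dates))


def temporal_max_composite(stack: RasterStack) -> np.ndarray:
    """Per-pixel maximum °C over the stack, excluding missing pixels.

    Pixels with no valid observation on any day stay NaN.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    decoded = decode_lst(stack.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(decoded, axis=0)


# ---------------------------------------------------------------------------
# chained-equation imputation of missing province-day temperature maxima
# ---------------------------------------------------------------------------

TEMP_COLS = ("temp_day", "temp_night")


def impute_panel(panel: pd.DataFrame, n_imputations: int = 5, n_cycles: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Complete missing province-day temperature maxima by chained equations.

    Cloud-contaminated days leave some provinces without a temperature
    maximum.  The panel is pivoted wide (one row per date, one column per
    province and phase) and each incomplete column is regressed on the others
    plus calendar covariates, cycling ``n_cycles`` times; ``n_imputations``
    completed datasets are averaged.  Observed values are never altered.

    Missingness is only allowed in the temperature columns, each
    province/phase column must be at least half observed, and a column with no
    observed values at all is an error.
    """
    from statsmodels.imputation.mice import MICEData

    panel = panel.copy()
    non_temp = [c for c in panel.columns if c not in TEMP_COLS]
    if panel[non_temp].isna().any().any():
        raise ValueError("missingness only allowed in temperature columns")
    if not panel[list(TEMP_COLS)].isna().any().any():
        return panel

    wide = panel.pivot(index="date", columns="province", values=list(TEMP_COLS))
    wide.columns = [f"{phase[5:]}_{prov}" for phase, prov in wide.columns]
    obs_frac = wide.notna().mean()
    if (obs_frac == 0).any():
        raise ValueError("temperature column with zero observed values")
    if (obs_frac < 0.5).any():
        raise ValueError("each province needs at least 50% observed days")

    dates = wide.index
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy(dtype=float)
    wide = wide.assign(
        cal_sin=np.sin(2 * np.pi * doy / 365.25),
        cal_cos=np.cos(2 * np.pi * doy / 365.25),
        cal_year=pd.DatetimeIndex(dates).year.astype(float),
    )

    np.random.seed(seed % (2**31))  # MICEData draws from the global state
    mice = MICEData(wide.reset_index(drop=True), k_pmm=5)
    temp_cols = [c for c in wide.columns if not c.startswith("cal_")]
    acc = np.zeros((len(wide), len(temp_cols)))
    for _ in range(n_imputations):
        mice.update_all(n_cycles)
        acc += mice.data[temp_cols].to_numpy()
    filled = pd.DataFrame(acc / n_imputations, index=dates, columns=temp_cols)

    out = panel.copy()
    for col in TEMP_COLS:
        phase = col[5:]
        miss = out[col].isna()
        if miss.any():
            vals = [
                filled.at[d, f"{phase}_{p}"]
                for d, p in zip(out.loc[miss, "date"], out.loc[miss, "province"])
            ]
            out.loc[miss, col] = vals
    return out


# ---------------------------------------------------------------------------
# flat-binary persistence (gridded inputs/outputs travel as .npz + metadata)
# ---------------------------------------------------------------------------

def save_stack(path, stack: RasterStack) -> None:
    np.savez_compressed(
        path,
        values=stack.values,
        dates=np.array([str(d) for d in stack.dates]),
        phase=np.array(stack.phase),
    )


def load_stack(path) -> RasterStack:
    with np.load(path, allow_pickle=False) as z:
        dates = [Date.fromisoformat(str(d)) for d in z["dates"]]
        return RasterStack(z["values"], dates, str(z["phase"]))


def save_zones(path, zones: ZoneMap) -> None:
    items = sorted(zones.city_to_province.items())
    np.savez_compressed(
        path,
        province_labels=zones.province_labels,
        city_labels=zones.city_labels,
        city_ids=np.array([c for c, _ in items]),
        city_provs=np.array([p for _, p in items]),
        pixel_area=np.array(zones.pixel_area_km2),
    )


def load_zones(path) -> ZoneMap:
    with np.load(path, allow_pickle=False) as z:
        mapping = dict(zip(z["city_ids"].tolist(), z["city_provs"].tolist()))
        return ZoneMap(z["province_labels"], z["city_labels"], mapping,
                       float(z["pixel_area"]))
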