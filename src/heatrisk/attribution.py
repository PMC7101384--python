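"""Heat-attributable mortality density and HHRI validation.

City mortality is apportioned from province totals by population share,
converted to heat-attributable deaths through the attributable fraction
AF = (RR − 1)/RR at the 99th-percentile temperature (averaged between day and
night), expressed per km² of city land (NDAH), and correlated with the
composite risk index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def mortality_share(city_pop: float, province_pop: float,
                    province_mortality: float) -> float:
    """City share of province all-cause mortality, by population ratio."""
    if province_pop <= 0:
        raise ValueError("province population must be positive")
    if not (0 < city_pop <= province_pop):
        raise ValueError("city population must be in (0, province population]")
    return (city_pop / province_pop) * province_mortality


def attributable_fraction(rr: float) -> float:
    """AF = (RR − 1)/RR; zero at RR = 1, approaching 1 as RR grows."""
    if rr <= 0:
        raise ValueError("RR must be positive")
    return (rr - 1.0) / rr


def attributable_deaths(rr_day: float, rr_night: float, mortality: float) -> float:
    """Heat-attributable deaths x = AF × M, averaged between day and night.

    RR below 1 yields a negative contribution; it is retained (flagged with a
    warning) rather than truncated at zero.
    """
    x_day = attributable_fraction(rr_day) * mortality
    x_night = attributable_fraction(rr_night) * mortality
    x = 0.5 * (x_day + x_night)
    if x < 0:
        warnings.warn("negative attributable deaths (RR < 1) retained", UserWarning)
    return x


def ndah(x: float, area_km2: float) -> float:
    """Number of deaths attributable to heat per km² of city land."""
    if area_km2 <= 0:
        raise ValueError("city land area must be positive")
    return x / area_km2


@dataclass
class ValidationResult:
    r: float
    p_value: float
    n_used: int
    n_dropped: int
    scatter: pd.DataFrame

    def __repr__(self) -> str:  # keep the frame out of logs
        return (f"ValidationResult(r={self.r:.3f}, p={self.p_value:.2e}, "
                f"n={self.n_used}, dropped={self.n_dropped})")


def validate(hhri: pd.Series, ndah_values: pd.Series) -> ValidationResult:
    """Pearson correlation between per-city HHRI and NDAH.

    Pairs with a missing value on either side are dropped (and counted);
    at least three complete pairs with non-zero variance are required.
    """
    df = pd.DataFrame({"hhri": hhri, "ndah": ndah_values})
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if len(complete) < 3:
        raise ValueError("need at least 3 paired cities")
    if complete["hhri"].std() == 0 or complete["ndah"].std() == 0:
        raise ValueError("zero variance in HHRI or NDAH")
    r, p = stats.pearsonr(complete["hhri"], complete["ndah"])
    return ValidationResult(float(r), float(p), len(complete), n_dropped,
                            complete.reset_index(names="city"))
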