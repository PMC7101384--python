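"""Hazard / exposure / vulnerability indices and the weighted risk ensemble.

Follows the IPCC AR5 framing: risk is the weighted additive aggregate of a
heat hazard index (MMT-anchored surface-temperature composite), a heat
exposure index (population density), and a heat vulnerability index
(sensitivity vs. coping/adaptive capacity).  Relative weights come from
expert pairwise-comparison matrices via the analytic hierarchy process (AHP,
principal-eigenvector method); experts whose judgements are too incoherent
(consistency ratio above threshold) are screened out, and the surviving
assessments are averaged into an ensemble heat health risk index (HHRI) with
a t-based 95% confidence interval and a five-level category label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster import ZoneMap

#: Saaty's random consistency indices by matrix size.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32}

RISK_COMPONENTS = ("hazard", "exposure", "vulnerability")
VULN_COMPONENTS = ("sensitivity", "capacity")
SENSITIVITY_INDICATORS = ("young_prop", "old_prop", "poverty_incidence")
CAPACITY_INDICATORS = ("mean_evi", "city_net_income", "per_capita_income")

CATEGORIES = ("very low", "low", "moderate", "high", "very high")


class NormalizationWarning(UserWarning):
    """Constant (zero-range) input mapped to all-zero indices."""


def minmax_normalize(values, floor: float | None = None) -> np.ndarray:
    """Linear min–max rescaling to [0, 1], optionally anchored at a floor.

    Without a floor: (x − min) / (max − min).  With a floor (e.g. the MMT
    threshold for the hazard layer), values at or below it map to 0 and the
    rest scale linearly up to 1 at the maximum.  NaNs pass through; constant
    input yields all zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("no finite values to normalize")
    lo = float(np.nanmin(x)) if floor is None else float(floor)
    hi = float(np.nanmax(x))
    out = np.full(x.shape, np.nan)
    if hi <= lo:
        warnings.warn("zero-range input normalized to all zeros", NormalizationWarning)
        out[finite] = 0.0
        return out
    out[finite] = np.clip((x[finite] - lo) / (hi - lo), 0.0, 1.0)
    return out


def _series_minmax(s: pd.Series, floor=None) -> pd.Series:
    return pd.Series(minmax_normalize(s.to_numpy(), floor), index=s.index, name=s.name)


def categorize(index: float) -> str:
    """Five equal bins on [0, 1]; the upper limit of each bin is inclusive,
    so 0.80 is 'high' while 0.81 is 'very high', and 0 is 'very low'."""
    if not np.isfinite(index) or index < -1e-9 or index > 1 + 1e-9:
        raise ValueError(f"index {index} outside [0, 1]")
    v = min(max(float(index), 0.0), 1.0)
    for i, upper in enumerate((0.2, 0.4, 0.6, 0.8, 1.0)):
        if v <= upper + 1e-12:
            return CATEGORIES[i]
    return CATEGORIES[-1]  # pragma: no cover


# ---------------------------------------------------------------------------
# AHP weighting
# ---------------------------------------------------------------------------

@dataclass
class PairwiseMatrix:
    """Reciprocal positive pairwise-comparison matrix over named items."""

    items: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        n = len(self.items)
        if A.shape != (n, n):
            raise ValueError("matrix shape must match item count")
        if (A <= 0).any():
            raise ValueError("pairwise matrix must be strictly positive")
        if not np.allclose(np.diag(A), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if not np.allclose(A * A.T, 1.0, atol=1e-6):
            raise ValueError("matrix must be reciprocal (a_ij = 1/a_ji)")
        self.matrix = A


def ahp_weights(pm: PairwiseMatrix):
    """Principal-eigenvector weights and consistency ratio.

    Weights are the principal right eigenvector normalised to sum 1.
    CI = (λ_max − n)/(n − 1) and CR = CI / RI_n with Saaty's random indices;
    2×2 matrices are consistent by definition (CR = 0).
    """
    A = pm.matrix
    n = A.shape[0]
    if n < 2 or n > 7:
        raise ValueError("AHP supported for sizes 2-7")
    eigvals, eigvecs = np.linalg.eig(A)
    k = int(np.argmax(eigvals.real))
    lam = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()
    if n <= 2:
        return w, 0.0
    ci = (lam - n) / (n - 1)
    return w, max(float(ci / SAATY_RI[n]), 0.0)


def consistent_matrix(items, weights) -> PairwiseMatrix:
    """Build the perfectly consistent matrix a_ij = w_i / w_j."""
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return PairwiseMatrix(tuple(items), np.outer(w, 1.0 / w))


@dataclass
class WeightSet:
    """One expert's hierarchical relative weights; every group sums to 1."""

    expert_id: int
    risk: np.ndarray          # (hazard, exposure, vulnerability)
    vulnerability: np.ndarray  # (sensitivity, capacity)
    sensitivity: np.ndarray   # per SENSITIVITY_INDICATORS
    capacity: np.ndarray      # per CAPACITY_INDICATORS
    crs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("risk", "vulnerability", "sensitivity", "capacity"):
            w = np.asarray(getattr(self, name), dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must be >= 0 and sum to 1")
            setattr(self, name, w)

    @property
    def max_cr(self) -> float:
        return max(self.crs.values()) if self.crs else 0.0


def weights_from_matrices(expert_id: int, matrices: dict) -> WeightSet:
    """Derive a WeightSet from an expert's group of pairwise matrices.

    ``matrices`` maps group name ('risk', 'vulnerability', 'sensitivity',
    'capacity') to a PairwiseMatrix; each group's CR is recorded for
    screening.
    """
    out, crs = {}, {}
    for group in ("risk", "vulnerability", "sensitivity", "capacity"):
        w, cr = ahp_weights(matrices[group])
        out[group] = w
        crs[group] = cr
    return WeightSet(expert_id, out["risk"], out["vulnerability"],
                     out["sensitivity"], out["capacity"], crs)


def screen_experts(weight_sets, cr_threshold: float = 0.1):
    """Retain an expert only if every one of their matrices has CR <= threshold."""
    return [ws for ws in weight_sets
            if all(cr <= cr_threshold for cr in ws.crs.values())]


# ---------------------------------------------------------------------------
# component indices
# ---------------------------------------------------------------------------

def _city_means(pixel_values: np.ndarray, zones: ZoneMap) -> pd.Series:
    out = {}
    for cid in zones.city_ids():
        vals = pixel_values[zones.city_labels == cid]
        vals = vals[np.isfinite(vals)]
        out[cid] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(out)


def hazard_index(day_composite, night_composite, mmt_day: float,
                 mmt_night: float, zones: ZoneMap) -> pd.Series:
    """Per-city heat hazard index anchored at the MMT thresholds.

    City pixels are extracted, each phase's composite is min–max normalised
    with its MMT as the floor (LST <= MMT maps to hazard 0), the two phase
    maps are averaged pixelwise, city means are taken over valid pixels, and
    the city values are re-normalised to [0, 1].  Cities with no valid pixel
    come back NaN with a warning.
    """
    if not (np.isfinite(mmt_day) and np.isfinite(mmt_night)):
        raise ValueError("MMT thresholds must be finite")
    day = np.asarray(day_composite, dtype=float)
    night = np.asarray(night_composite, dtype=float)
    if day.shape != zones.shape or night.shape != zones.shape:
        raise ValueError("composites and zone map must align")
    in_city = zones.city_labels >= 0
    day_city = np.where(in_city, day, np.nan)
    night_city = np.where(in_city, night, np.nan)
    norm_day = minmax_normalize(day_city, floor=mmt_day)
    norm_night = minmax_normalize(night_city, floor=mmt_night)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        averaged = np.nanmean(np.stack([norm_day, norm_night]), axis=0)
    city = _city_means(averaged, zones)
    if city.isna().any():
        warnings.warn(f"cities with no valid pixels: {city[city.isna()].index.tolist()}",
                      UserWarning)
    return _series_minmax(city)


def exposure_index(pop_density, zones: ZoneMap = None) -> pd.Series:
    """Per-city heat exposure index from population density.

    Accepts either a density grid aligned to the zone map (pixel densities
    are normalised, averaged per city, then re-normalised across cities) or a
    per-city density Series (normalised directly).
    """
    if isinstance(pop_density, pd.Series):
        return _series_minmax(pop_density.astype(float))
    if zones is None:
        raise ValueError("a zone map is required with a density grid")
    dens = np.asarray(pop_density, dtype=float)
    if (dens < 0).any():
        raise ValueError("population density must be non-negative")
    if dens.shape != zones.shape:
        raise ValueError("density grid and zone map must align")
    dens_city = np.where(zones.city_labels >= 0, dens, np.nan)
    normalized = minmax_normalize(dens_city)
    return _series_minmax(_city_means(normalized, zones))


def vulnerability_index(table: pd.DataFrame, ws: WeightSet) -> pd.Series:
    """Per-city vulnerability under one expert's weights.

    Indicators are min–max normalised across cities; sensitivity S and
    capacity C are their weighted sums; the capacity index is inverted
    (higher capacity, lower vulnerability): V_raw = w_S·S + w_C·(1−C),
    re-normalised across cities.
    """
    needed = SENSITIVITY_INDICATORS + CAPACITY_INDICATORS
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"indicator table lacks columns {missing}")
    if table[list(needed)].isna().any().any():
        raise ValueError("missing indicator value for some city")
    norm = {c: minmax_normalize(table[c].to_numpy()) for c in needed}
    S = sum(w * norm[c] for w, c in zip(ws.sensitivity, SENSITIVITY_INDICATORS))
    C = sum(w * norm[c] for w, c in zip(ws.capacity, CAPACITY_INDICATORS))
    v_raw = ws.vulnerability[0] * S + ws.vulnerability[1] * (1.0 - C)
    idx = table["city"] if "city" in table.columns else table.index
    return pd.Series(minmax_normalize(v_raw), index=idx, name="vulnerability")


def aggregate_risk(hazard, exposure, vulnerability, risk_weights) -> pd.Series:
    """Weighted additive risk: RI_i = w_H·H_i + w_E·E_i + w_V·V_i."""
    w = np.asarray(risk_weights, dtype=float)
    if w.shape != (3,) or abs(w.sum() - 1.0) > 1e-6 or (w < 0).any():
        raise ValueError("risk weights must be 3 non-negative values summing to 1")
    H, E, V = (pd.Series(v).astype(float) for v in (hazard, exposure, vulnerability))
    for s in (H, E, V):
        vals = s.dropna()
        if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
            raise ValueError("component indices must lie in [0, 1]")
    return w[0] * H + w[1] * E + w[2] * V


def ensemble_hhri(per_expert_ri: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Average per-expert risk indices into the overall HHRI per city.

    Columns are experts, rows are cities.  The 95% CI is
    mean ± t_{1−α/2, k−1}·SD/√k over the k experts; with fewer than two
    experts the CI is flagged unavailable (NaN bounds).
    """
    k = per_expert_ri.shape[1]
    mean = per_expert_ri.mean(axis=1)
    if k >= 2:
        sd = per_expert_ri.std(axis=1, ddof=1)
        half = stats.t.ppf(1 - alpha / 2, k - 1) * sd / np.sqrt(k)
        lo, hi = mean - half, mean + half
    else:
        warnings.warn("fewer than 2 experts: CI unavailable", UserWarning)
        lo = hi = pd.Series(np.nan, index=mean.index)
    out = pd.DataFrame({"hhri": mean, "ci_low": lo, "ci_high": hi})
    out["category"] = mean.map(categorize)
    return out


def risk_table(hazard: pd.Series, exposure: pd.Series, table: pd.DataFrame,
               weight_sets) -> pd.DataFrame:
    """Assemble the full per-city risk table over an expert ensemble.

    For each retained expert: a vulnerability index under their indicator and
    component weights, then RI via their risk-component weights; finally the
    ensemble mean HHRI, its CI, and the category label.
    """
    if not weight_sets:
        raise ValueError("no experts retained")
    ri_cols, v_cols = {}, {}
    for ws in weight_sets:
        V = vulnerability_index(table, ws)
        V.index = hazard.index
        v_cols[ws.expert_id] = V
        ri_cols[ws.expert_id] = aggregate_risk(hazard, exposure, V, ws.risk)
    ri = pd.DataFrame(ri_cols)
    out = pd.DataFrame({"hazard": hazard, "exposure": exposure,
                        "vulnerability_mean": pd.DataFrame(v_cols).mean(axis=1)})
    for eid in ri.columns:
        out[f"ri_expert_{eid}"] = ri[eid]
    return pd.concat([out, ensemble_hhri(ri)], axis=1)
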