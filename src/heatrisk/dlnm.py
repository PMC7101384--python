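"""Distributed-lag non-linear modelling of temperature and mortality.

Daily province-level all-cause death counts are regressed on a crossbasis in
temperature — the tensor product of a natural cubic spline in the exposure
dimension (4 df, knots at equally spaced quantiles of observed temperature)
and a lag basis over 0..``lag_max`` days (intercept plus three natural-spline
curvature terms with internal knots equally spaced on the log lag scale) —
with a quasi-Poisson likelihood (log link, variance proportional to the mean).
Covariates: province intercepts, a linear secular trend per province, day of
week, a holiday flag, and a 4-df natural cubic spline in mean relative
humidity.

From the fitted crossbasis coefficients we derive the cumulative (lag-summed)
relative-risk curve, locate the minimum-mortality temperature (MMT) on a dense
grid, re-centre the curve at the MMT so RR(MMT) = 1 exactly, and read off the
RR at the 99th percentile of the temperature data, the quantity used
downstream for heat-attributable deaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


def natural_spline(x, knots, intercept: bool = False, drop_linear: bool = False) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form, linear beyond the
    outermost knots).

    ``knots`` is the full increasing knot sequence including boundaries; with
    K knots the basis has K−2 curvature columns plus (optionally) linear and
    intercept columns.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or len(k) < 3 or np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing with length >= 3")

    def d(j: int) -> np.ndarray:
        return (
            np.clip(x - k[j], 0.0, None) ** 3 - np.clip(x - k[-1], 0.0, None) ** 3
        ) / (k[-1] - k[j])

    d_last = d(len(k) - 2)
    cols = []
    if intercept:
        cols.append(np.ones_like(x))
    if not drop_linear:
        cols.append(x)
    cols.extend(d(j) - d_last for j in range(len(k) - 2))
    return np.column_stack(cols)


def quantile_knots(x, df: int) -> np.ndarray:
    """Boundary plus df−1 internal knots at equally spaced quantiles."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    probs = np.linspace(0, 1, df + 1)
    k = np.quantile(x, probs)
    if np.any(np.diff(k) <= 0):
        raise ValueError("degenerate quantile knots (too many ties in data)")
    return k


@dataclass
class CrossbasisSpec:
    """Shape of the exposure–lag crossbasis.

    ``exposure_df`` natural-spline df in the exposure dimension (knots at
    equally spaced temperature quantiles); the lag dimension uses an intercept
    plus natural-spline curvature terms from ``lag_knots`` internal knots
    equally spaced on the log lag scale, for ``1 + lag_knots`` lag columns.
    """

    exposure_df: int = 4
    lag_max: int = 14
    lag_knots: int = 3

    def __post_init__(self) -> None:
        if self.exposure_df < 2:
            raise ValueError("exposure_df must be >= 2")
        if self.lag_max < 1:
            raise ValueError("lag_max must be >= 1")

    @property
    def lag_knot_values(self) -> np.ndarray:
        """Internal lag knots, equally spaced in log(lag), inside (0, lag_max)."""
        return np.exp(np.linspace(0.0, np.log(self.lag_max), self.lag_knots + 2))[1:-1]

    @property
    def lag_dim(self) -> int:
        return 1 + self.lag_knots

    def lag_basis(self) -> np.ndarray:
        """(lag_max+1, lag_dim) basis over lags 0..lag_max."""
        lags = np.arange(self.lag_max + 1, dtype=float)
        knots = np.concatenate([[0.0], self.lag_knot_values, [float(self.lag_max)]])
        return natural_spline(lags, knots, intercept=True, drop_linear=True)


@dataclass
class Crossbasis:
    """Evaluated crossbasis block plus everything needed to predict from it."""

    X: np.ndarray           # (n, exposure_df * lag_dim)
    valid: np.ndarray       # rows with a full lag history inside their block
    spec: CrossbasisSpec
    exposure_knots: np.ndarray
    temps: np.ndarray       # the exposure series the basis was built from

    @property
    def ncols(self) -> int:
        return self.X.shape[1]

    def exposure_basis(self, temps) -> np.ndarray:
        return natural_spline(np.asarray(temps, float), self.exposure_knots)

    def prediction_matrix(self, temps) -> np.ndarray:
        """Rows mapping crossbasis coefficients to cumulative log-RR at each
        temperature (exposure basis × lag basis summed over lags)."""
        lag_sum = self.spec.lag_basis().sum(axis=0)          # (lag_dim,)
        R = self.exposure_basis(temps)                        # (g, exposure_df)
        return np.einsum("gj,k->gjk", R, lag_sum).reshape(len(R), -1)


def build_crossbasis(temps, groups, spec: CrossbasisSpec,
                     exposure_knots=None) -> Crossbasis:
    """Evaluate the crossbasis for a concatenated multi-group daily series.

    ``groups`` labels contiguous blocks (e.g. one province-season); lagging
    never crosses a block boundary, and the first ``lag_max`` rows of each
    block are flagged invalid.  Each block must be longer than ``lag_max``.
    """
    temps = np.asarray(temps, dtype=float)
    groups = np.asarray(groups)
    if len(temps) != len(groups):
        raise ValueError("temps and groups must align")
    L = spec.lag_max
    n = len(temps)
    Q = np.full((n, L + 1), np.nan)
    # block boundaries: change points in the group labels
    change = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    bounds = np.r_[change, n]
    for s, e in zip(bounds[:-1], bounds[1:]):
        block = temps[s:e]
        if len(block) < L + 1:
            raise ValueError(
                f"series of length {len(block)} shorter than lag_max+1 = {L + 1}"
            )
        for lag in range(L + 1):
            Q[s + lag : e, lag] = block[: e - s - lag]
    valid = ~np.isnan(Q).any(axis=1)
    if exposure_knots is None:
        exposure_knots = quantile_knots(temps, spec.exposure_df)
    Qf = np.where(np.isnan(Q), exposure_knots[0], Q)
    R = natural_spline(Qf.ravel(), exposure_knots).reshape(n, L + 1, spec.exposure_df)
    C = spec.lag_basis()                                      # (L+1, lag_dim)
    X = np.einsum("nlj,lk->njk", R, C).reshape(n, -1)
    return Crossbasis(X, valid, spec, np.asarray(exposure_knots), temps)


@dataclass
class ModelFit:
    """A fitted quasi-Poisson DLNM with its design bookkeeping."""

    result: object                 # statsmodels GLMResults
    crossbasis: Crossbasis
    cb_index: np.ndarray           # columns of the crossbasis block in X
    X: np.ndarray
    y: np.ndarray
    col_names: list
    phase: str
    temps_used: np.ndarray         # exposure values on the fitted rows

    @property
    def dispersion(self) -> float:
        """Pearson-residual dispersion estimate (phi in var = phi * mu)."""
        return float(self.result.scale)

    @property
    def cb_params(self) -> np.ndarray:
        return np.asarray(self.result.params)[self.cb_index]

    @property
    def cb_cov(self) -> np.ndarray:
        return np.asarray(self.result.cov_params())[np.ix_(self.cb_index, self.cb_index)]


def _dow_dummies(dates: pd.DatetimeIndex):
    dow = dates.dayofweek.to_numpy()
    cols = [(dow == d).astype(float) for d in range(1, 7)]  # Monday reference
    names = ["dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat", "dow_sun"]
    return np.column_stack(cols), names


def fit_model(panel: pd.DataFrame, spec: CrossbasisSpec, phase: str = "day",
              rh_df: int = 4) -> ModelFit:
    """Fit the quasi-Poisson crossbasis model for one diurnal phase.

    ``panel`` needs columns province, date, deaths, temp_day, temp_night, rh,
    holiday; dates must be contiguous within each province-season block.
    Provinces are fitted jointly with province intercepts and per-province
    linear secular trends; day and night enter separate models.
    """
    if phase not in ("day", "night"):
        raise ValueError("phase must be 'day' or 'night'")
    temp_col = f"temp_{phase}"
    for col in ("province", "date", "deaths", temp_col, "rh", "holiday"):
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    df = panel.sort_values(["province", "date"]).reset_index(drop=True)
    if df[temp_col].isna().any():
        raise ValueError("temperature series has missing values; impute first")
    dates = pd.DatetimeIndex(df["date"])

    blocks = df["province"].astype(str) + "/" + dates.year.astype(str)
    cb = build_crossbasis(df[temp_col].to_numpy(), blocks.to_numpy(), spec)

    provinces = sorted(df["province"].unique())
    prov = df["province"].to_numpy()
    day_index = (dates - dates.min()).days.to_numpy() / 365.25
    parts = [np.ones((len(df), 1))]
    names = ["const"]
    parts.append(cb.X)
    names += [f"cb_{j}" for j in range(cb.ncols)]
    for p in provinces[1:]:
        parts.append((prov == p).astype(float)[:, None])
        names.append(f"prov_{p}")
    for p in provinces:
        parts.append((day_index * (prov == p))[:, None])
        names.append(f"trend_{p}")
    dow, dow_names = _dow_dummies(dates)
    parts.append(dow)
    names += dow_names
    parts.append(df["holiday"].to_numpy(dtype=float)[:, None])
    names.append("holiday")
    rh_basis = natural_spline(df["rh"].to_numpy(), quantile_knots(df["rh"], rh_df))
    parts.append(rh_basis)
    names += [f"rh_{j}" for j in range(rh_basis.shape[1])]

    X = np.hstack(parts)
    keep = cb.valid
    Xk, yk = X[keep], df["deaths"].to_numpy(dtype=float)[keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(yk, Xk, family=sm.families.Poisson())
    result = model.fit(scale="X2", maxiter=300, tol=1e-10)
    if not result.converged:
        # accept a machine-precision deviance plateau as converged
        dev = np.asarray(result.fit_history["deviance"][-5:])
        if np.ptp(dev) > 1e-8 * max(abs(dev[-1]), 1.0):
            raise RuntimeError("quasi-Poisson IRLS failed to converge")
    cb_index = np.arange(1, 1 + cb.ncols)
    return ModelFit(result, cb, cb_index, Xk, yk, names, phase,
                    df[temp_col].to_numpy()[keep])


@dataclass
class RRCurve:
    """Cumulative relative-risk curve with delta-method pointwise CI."""

    temps: np.ndarray
    rr: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    reference: float
    rr_p99: float = np.nan
    mmt_flat: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temp_c": self.temps, "rr": self.rr, "rr_low": self.rr_low,
             "rr_high": self.rr_high}
        )


def predict_rr(fit: ModelFit, temp_grid, reference: float,
               alpha: float = 0.05) -> RRCurve:
    """Cumulative RR over all lags at each grid temperature, relative to the
    reference temperature, with delta-method pointwise confidence bands."""
    grid = np.asarray(temp_grid, dtype=float)
    tmin, tmax = fit.temps_used.min(), fit.temps_used.max()
    if not (tmin <= reference <= tmax):
        raise ValueError("reference outside the observed temperature range")
    P = fit.crossbasis.prediction_matrix(grid)
    P_ref = fit.crossbasis.prediction_matrix([reference])
    Pc = P - P_ref
    log_rr = Pc @ fit.cb_params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Pc, fit.cb_cov, Pc))
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return RRCurve(grid, np.exp(log_rr), np.exp(log_rr - z * se),
                   np.exp(log_rr + z * se), float(reference))


@dataclass
class MMTResult:
    mmt: float
    flat: bool
    grid: np.ndarray = field(repr=False, default=None)


def _grid_argmin(values: np.ndarray, grid: np.ndarray, tol: float = 1e-10):
    """Index of the minimum; ties (within tol) break toward the lower
    temperature, which np.argmin's first-hit rule provides on a sorted grid."""
    flat = bool((values.max() - values.min()) < tol)
    return int(np.argmin(values)), flat


def find_mmt(fit: ModelFit, search_range=None, step: float = 0.1) -> MMTResult:
    """Temperature minimising the cumulative response on a dense grid.

    The search is confined to the 1st–99th percentile band of the observed
    temperatures (boundary artefacts from sparse tails are not meaningful
    minima); a flat response is reported with a warning flag.
    """
    if search_range is None:
        lo, hi = np.percentile(fit.temps_used, [1, 99])
    else:
        lo, hi = search_range
        tmin, tmax = fit.temps_used.min(), fit.temps_used.max()
        if lo < tmin or hi > tmax:
            raise ValueError("search range outside observed temperatures")
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    curve = predict_rr(fit, grid, reference=grid[0])
    idx, flat = _grid_argmin(np.log(curve.rr), grid)
    if flat:
        warnings.warn("flat cumulative response: MMT not unique", RuntimeWarning)
    return MMTResult(float(grid[idx]), flat, grid)


@dataclass
class PhaseResult:
    """One phase's fitted model, MMT, and MMT-centred RR curve."""

    fit: ModelFit
    mmt: float
    mmt_flat: bool
    curve: RRCurve
    p99: float
    rr_p99: float


def fit_phase(panel: pd.DataFrame, spec: CrossbasisSpec = None,
              phase: str = "day") -> PhaseResult:
    """Fit, locate the MMT, and re-centre: RR(MMT) = 1 by construction."""
    spec = spec or CrossbasisSpec()
    fit = fit_model(panel, spec, phase=phase)
    res = find_mmt(fit)
    curve = predict_rr(fit, res.grid, reference=res.mmt)
    curve.mmt_flat = res.flat
    p99 = float(np.percentile(fit.temps_used, 99))
    rr_p99 = float(predict_rr(fit, [p99], reference=res.mmt).rr[0])
    curve.rr_p99 = rr_p99
    return PhaseResult(fit, res.mmt, res.flat, curve, p99, rr_p99)


def wald_crossbasis_pvalue(fit: ModelFit) -> float:
    """Quasi-F Wald test of the whole crossbasis block being zero."""
    R = np.zeros((len(fit.cb_index), fit.X.shape[1]))
    R[np.arange(len(fit.cb_index)), fit.cb_index] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        test = fit.result.wald_test(R, use_f=True, scalar=True)
    return float(test.pvalue)
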