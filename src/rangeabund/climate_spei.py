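"""Thornthwaite potential evapotranspiration and the 12-month SPEI.

The standardized precipitation-evapotranspiration index (SPEI) turns the
12-month running water balance ``sum(P - PET)`` into a standard-normal
deviate: positive = humid, negative = dry. Per calendar month, the
12-month sums are fitted with a three-parameter log-logistic distribution
by unbiased probability-weighted moments and mapped through the fitted
CDF and the inverse normal CDF.

PET uses the Thornthwaite method: from monthly mean temperature and
latitude only. The annual heat index is computed from the climatological
monthly mean temperatures of the supplied series, and the day-length
correction uses the mean-day solar declination per month -- sub-daily
precision is irrelevant at a monthly scale.

Climate series are DataFrames with columns
``plot_id, latitude, year, month, tmean_c, prec_mm`` sorted by time,
with contiguous months.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

logger = logging.getLogger(__name__)

DAYS_IN_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# mean day of year per calendar month, used for solar declination
MID_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


class ClimateError(ValueError):
    pass


def _check_contiguous(year: np.ndarray, month: np.ndarray) -> None:
    idx = year * 12 + (month - 1)
    if len(idx) < 2:
        return
    if not np.all(np.diff(idx) == 1):
        raise ClimateError("climate series has gaps or is unsorted")


def day_length_hours(latitude: float, month_index: np.ndarray) -> np.ndarray:
    """Mean day length (h) per calendar month at ``latitude`` (degrees).

    Solar declination at the month's mean day; sunset hour angle clamped
    for polar day/night.
    """
    phi = np.deg2rad(latitude)
    delta = 0.409 * np.sin(2 * np.pi / 365.25 * MID_DOY[month_index] - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def thornthwaite_pet(series: pd.DataFrame) -> np.ndarray:
    """Monthly Thornthwaite PET (mm) for one plot's climate series.

    heat index  I = sum_m (Tbar_m / 5)^1.514 over climatological monthly
    means Tbar_m > 0; exponent a = 6.75e-7 I^3 - 7.71e-5 I^2
    + 1.792e-2 I + 0.49239; PET_m = 16 K_m (10 T_m / I)^a for T_m > 0,
    else 0, with K_m = (N_m / 12)(days_m / 30) the day-length and
    month-length correction.
    """
    lat = float(series["latitude"].iloc[0])
    t = series["tmean_c"].to_numpy(dtype=float)
    month_index = series["month"].to_numpy(dtype=int) - 1
    _check_contiguous(series["year"].to_numpy(int), series["month"].to_numpy(int))

    monthly_means = np.full(12, np.nan)
    for m in range(12):
        sel = month_index == m
        if sel.any():
            monthly_means[m] = t[sel].mean()
    tbar = np.clip(np.nan_to_num(monthly_means), 0.0, None)
    heat_index = float(((tbar / 5.0) ** 1.514).sum())
    if heat_index <= 0:
        warnings.warn("all monthly mean temperatures <= 0 degC; PET is all zero")
        return np.zeros_like(t)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    K = day_length_hours(lat, month_index) / 12.0 * DAYS_IN_MONTH[month_index] / 30.0
    pet = np.where(t > 0, 16.0 * K * (10.0 * np.clip(t, 0, None) / heat_index) ** a, 0.0)
    return pet


def water_balance_12(series: pd.DataFrame, pet: np.ndarray) -> pd.DataFrame:
    """Trailing 12-month sums of P - PET.

    The sum for a month covers that month and the 11 preceding ones; the
    first 11 months carry no value and are dropped. Returns columns
    ``year, month, wb12``.
    """
    _check_contiguous(series["year"].to_numpy(int), series["month"].to_numpy(int))
    if len(series) < 12:
        raise ClimateError("need at least 12 months for a 12-month water balance")
    d = series["prec_mm"].to_numpy(dtype=float) - np.asarray(pet, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(d)])
    wb = csum[12:] - csum[:-12]
    return pd.DataFrame(
        {
            "year": series["year"].to_numpy(int)[11:],
            "month": series["month"].to_numpy(int)[11:],
            "wb12": wb,
        }
    )


@dataclass
class LogLogisticParams:
    """Three-parameter log-logistic: F(x) = [1 + (alpha/(x-gamma))^beta]^-1.

    ``mirrored`` marks a fit to the negated sample (used when the sample
    is left-skewed, where the plain moment fit has no valid solution);
    the effective CDF is then ``1 - F(-x)``, still increasing in x.
    """

    beta: float  # shape
    alpha: float  # scale, > 0
    gamma: float  # origin
    mirrored: bool = False

    def _raw_cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = np.clip(x - self.gamma, 1e-12, None)
        return 1.0 / (1.0 + (self.alpha / z) ** self.beta)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        if self.mirrored:
            return 1.0 - self._raw_cdf(-np.asarray(x, dtype=float))
        return self._raw_cdf(x)

    @property
    def origin(self) -> float:
        """Lower support bound of the effective distribution (-inf if mirrored)."""
        return -np.inf if self.mirrored else self.gamma


def _unbiased_pwm(x: np.ndarray, s: int) -> float:
    """Unbiased estimator of the probability-weighted moment w_s = E[X (1-F)^s].

    The (1-F)-type moments are the convention of the log-logistic
    moment-matching formulas below.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    w = np.ones(n)
    for r in range(s):
        w = w * (n - i - r) / (n - 1 - r)
    return float((w * x).sum() / n)


def fit_loglogistic(x: np.ndarray, _allow_mirror: bool = True) -> LogLogisticParams:
    """Fit the 3-parameter log-logistic by unbiased probability-weighted moments.

    A left-skewed sample has no valid moment solution (the implied shape
    turns negative); it is then fitted after negation and flagged
    ``mirrored``, which reflects the CDF and keeps standardization
    monotone.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 or np.ptp(x) == 0:
        raise ClimateError("need >= 4 distinct water-balance values to fit")
    b0, b1, b2 = (_unbiased_pwm(x, s) for s in range(3))
    denom = 6.0 * b1 - b0 - 6.0 * b2
    beta = (2.0 * b1 - b0) / denom if denom != 0 else np.nan
    alpha = gamma0 = np.nan
    if np.isfinite(beta) and beta > 1.0:
        g12 = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)
        alpha = (b0 - 2.0 * b1) * beta / g12
        gamma0 = b0 - alpha * g12
    if not (np.isfinite(alpha) and alpha > 0):
        if not _allow_mirror:
            raise ClimateError(
                f"no valid log-logistic moment fit (beta={beta:.4g}, alpha={alpha:.4g})"
            )
        mirrored = fit_loglogistic(-x, _allow_mirror=False)
        mirrored.mirrored = True
        return mirrored
    return LogLogisticParams(beta=beta, alpha=alpha, gamma=gamma0)


def fit_monthly_params(wb: pd.DataFrame) -> dict[int, LogLogisticParams]:
    """Fit per-calendar-month log-logistic parameters to 12-month sums."""
    params: dict[int, LogLogisticParams] = {}
    for m, grp in wb.groupby("month"):
        vals = grp["wb12"].to_numpy(dtype=float)
        if len(vals) < 10:
            warnings.warn(f"only {len(vals)} values for calendar month {m}; fit is noisy")
        params[int(m)] = fit_loglogistic(vals)
    return params


# Abramowitz & Stegun 26.2.23 rational approximation to the normal quantile;
# max abs error ~4.5e-4, the convention used by standard SPEI implementations.
_C = (2.515517, 0.802853, 0.010328)
_D = (1.432788, 0.189269, 0.001308)


def normal_quantile(p: np.ndarray) -> np.ndarray:
    """Phi^-1(p) via the Abramowitz-Stegun rational approximation."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    lower = p < 0.5
    pp = np.where(lower, p, 1.0 - p)
    t = np.sqrt(-2.0 * np.log(pp))
    num = _C[0] + _C[1] * t + _C[2] * t * t
    den = 1.0 + _D[0] * t + _D[1] * t * t + _D[2] * t**3
    z = t - num / den
    return np.where(lower, -z, z)


def spei(
    wb: pd.DataFrame,
    params: dict[int, LogLogisticParams],
    clamp: float = 3.0,
) -> pd.DataFrame:
    """Standardize 12-month water-balance sums to SPEI values.

    Values below a month's fitted origin have an undefined CDF and are
    clamped to ``-clamp`` (and symmetrically at the top) with a warning.
    Returns columns ``year, month, spei12``.
    """
    out = np.empty(len(wb))
    clamped = 0
    months = wb["month"].to_numpy(int)
    vals = wb["wb12"].to_numpy(float)
    for m in np.unique(months):
        sel = months == m
        pm = params[int(m)]
        x = vals[sel]
        below = x <= pm.origin
        clamped += int(below.sum())
        z = normal_quantile(pm.cdf(x))
        z = np.where(below, -clamp, np.clip(z, -clamp, clamp))
        out[sel] = z
    if clamped:
        warnings.warn(f"{clamped} water-balance values below fitted origin; clamped to -{clamp}")
    return pd.DataFrame({"year": wb["year"], "month": wb["month"], "spei12": out})


def spei_series(series: pd.DataFrame, clamp: float = 3.0) -> pd.DataFrame:
    """End-to-end SPEI for one plot: PET -> 12-month balance -> standardization."""
    pet = thornthwaite_pet(series)
    wb = water_balance_12(series, pet)
    params = fit_monthly_params(wb)
    return spei(wb, params, clamp=clamp)


def plot_mean_spei(
    climate: pd.DataFrame, window_months: int = 120
) -> pd.Series:
    """Per-plot SPEI predictor: mean monthly SPEI over a trailing window.

    The log-logistic calibration uses each plot's full series; averaging
    over the final ``window_months`` (default 10 years) yields the
    plot-level humidity covariate used in the regression.
    """
    means = {}
    for pid, series in climate.groupby("plot_id", sort=False):
        s = spei_series(series.sort_values(["year", "month"]))
        means[pid] = float(s["spei12"].tail(window_months).mean())
    return pd.Series(means, name="spei")


def optimal_spei(native_spei_values: np.ndarray) -> float:
    """Species' optimal SPEI: mean plot SPEI over its native-range plots."""
    v = np.asarray(native_spei_values, dtype=float)
    if v.size == 0:
        raise ClimateError("species has no native-range plots with SPEI")
    return float(v.mean())


def spei_dissimilarity(local: float, optimal: float) -> float:
    """Distance of local conditions from the species' climatic optimum."""
    return abs(float(local) - float(optimal))
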