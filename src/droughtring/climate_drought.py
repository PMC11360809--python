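"""Thornthwaite PET, climatic water balance, SPEI and drought calendars.

The Standardized Precipitation-Evapotranspiration Index (SPEI) at time
scale ``k`` standardizes the rolling ``k``-month sum of the climatic
water balance D = P - PET.  Per calendar month, a 3-parameter
log-logistic distribution is fitted to the aggregated balances by
unbiased probability-weighted moments (the L-moment route used by the
reference SPEI implementation), and the fitted non-exceedance
probability is mapped to a standard normal deviate with the classical
Abramowitz-Stegun rational approximation.  PET comes from the
Thornthwaite temperature-only formula with the day-length/month-length
correction for the site latitude.

Drought classes follow the SPEI convention with continuous half-open
bands: moderate (-1.5, -1], severe (-2, -1.5], extreme <= -2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: SPEI breakpoints for moderate / severe / extreme drought
DEFAULT_DROUGHT_THRESHOLDS = (-1.0, -1.5, -2.0)

DROUGHT_CLASSES = ("moderate", "severe", "extreme")


class ClimateDataError(ValueError):
    """Invalid or incomplete monthly climate input."""


class SpeiError(ValueError):
    """SPEI standardization failed (degenerate month or invalid parameters)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ClimateSeries:
    """One site's monthly temperature/precipitation record.

    ``data`` columns: year, month, tmean (deg C), prec (mm), and, once
    :func:`thornthwaite_pet` has been applied, pet and balance (mm/month).
    Months must be complete January-December for every year.
    """

    site_id: str
    latitude: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"year", "month", "tmean", "prec"}
        if not required.issubset(df.columns):
            raise ClimateDataError(f"climate table needs columns {sorted(required)}")
        df = df.sort_values(["year", "month"]).reset_index(drop=True)
        for year, grp in df.groupby("year"):
            if sorted(grp["month"]) != list(range(1, 13)):
                raise ClimateDataError(f"site {self.site_id!r}: year {year} is not "
                                       "complete January-December")
        if np.any(df["prec"].to_numpy() < 0):
            raise ClimateDataError("negative precipitation")
        self.data = df

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].to_numpy())

    @property
    def span(self) -> tuple[int, int]:
        y = self.years
        return int(y[0]), int(y[-1])

    def annual_summary(self) -> pd.DataFrame:
        """MAT (mean of 12 monthly tmean, deg C) and AP (sum of monthly prec, mm)."""
        g = self.data.groupby("year")
        return pd.DataFrame({"mat": g["tmean"].mean(), "ap": g["prec"].sum()}).reset_index()

    def monthly(self, column: str) -> pd.DataFrame:
        """Year-by-month pivot of one column."""
        return self.data.pivot(index="year", columns="month", values=column)


@dataclass
class SpeiSeries:
    """Standardized k-month water-balance index per (year, month)."""

    site_id: str
    scale: int
    data: pd.DataFrame  # columns: year, month, spei (NaN for the first k-1 months)

    def month_values(self, month: int) -> pd.Series:
        sel = self.data[self.data["month"] == month]
        return pd.Series(sel["spei"].to_numpy(), index=sel["year"].to_numpy()).dropna()


@dataclass
class DroughtCalendar:
    """Months classed moderate / severe / extreme for one site."""

    site_id: str
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["year", "month", "severity"]))

    def __post_init__(self) -> None:
        df = self.entries
        bad = set(df["severity"]) - set(DROUGHT_CLASSES)
        if bad:
            raise ValueError(f"unknown drought class(es): {sorted(bad)}")
        self.entries = df.sort_values(["year", "month"]).reset_index(drop=True)

    def year_class(self) -> pd.Series:
        """Worst month class per year (extreme > severe > moderate)."""
        if self.entries.empty:
            return pd.Series(dtype=object)
        rank = {c: i for i, c in enumerate(DROUGHT_CLASSES)}
        worst = self.entries.groupby("year")["severity"].agg(
            lambda s: max(s, key=rank.__getitem__))
        return worst

    def years_with(self, classes) -> list[int]:
        """Years containing at least one month of any of the given classes."""
        sel = self.entries[self.entries["severity"].isin(list(classes))]
        return sorted(set(sel["year"].astype(int)))

    def severe_or_extreme_years(self) -> list[int]:
        return self.years_with(("severe", "extreme"))

    def extreme_years(self) -> list[int]:
        return self.years_with(("extreme",))


# ---------------------------------------------------------------------------
# Thornthwaite PET
# ---------------------------------------------------------------------------

def _day_length_correction(latitude: float) -> np.ndarray:
    """K factor per month: (mean day length / 12 h) * (days in month / 30)."""
    mid_doy = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2
    delta = 0.4093 * np.sin(2 * np.pi * mid_doy / 365.25 - 1.405)  # solar declination
    lat = np.deg2rad(latitude)
    cos_omega = np.clip(-np.tan(lat) * np.tan(delta), -1.0, 1.0)
    day_len = 24.0 / np.pi * np.arccos(cos_omega)
    return (day_len / 12.0) * (DAYS_IN_MONTH / 30.0)


def thornthwaite_pet(series: ClimateSeries) -> ClimateSeries:
    """Monthly Thornthwaite PET and the water balance D = P - PET.

    Annual heat index I = sum over months with t > 0 of (t/5)^1.514;
    exponent a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239.
    Unadjusted PET is 0 for t <= 0, 16 (10 t / I)^a for 0 < t < 26.5 deg C
    and the Willmott high-temperature polynomial above; the result is
    scaled by the day-length/month-length correction for the latitude.
    """
    if not -60 <= series.latitude <= 60:
        raise ClimateDataError("latitude must lie in [-60, 60] degrees")
    k = _day_length_correction(series.latitude)
    df = series.data.copy()
    pet = np.zeros(len(df))
    for year, grp in df.groupby("year"):
        t = grp.sort_values("month")["tmean"].to_numpy()
        warm = t > 0
        heat_index = np.sum((t[warm] / 5.0) ** 1.514)
        if warm.any() and heat_index <= 0:  # impossible: every warm month contributes > 0
            raise SpeiError(f"internal: zero heat index with warm months in {year}")
        a = (6.75e-7 * heat_index ** 3 - 7.71e-5 * heat_index ** 2
             + 1.792e-2 * heat_index + 0.49239)
        e = np.zeros(12)
        mid = warm & (t < 26.5)
        e[mid] = 16.0 * (10.0 * t[mid] / heat_index) ** a
        hot = t >= 26.5
        e[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2
        pet[grp.sort_values("month").index] = e * k
    df["pet"] = pet
    df["balance"] = df["prec"] - df["pet"]
    return ClimateSeries(site_id=series.site_id, latitude=series.latitude, data=df)


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def _loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic by unbiased probability-weighted moments.

    Uses Hosking's generalized-logistic (L-moment) parameterization
    (location xi, scale alpha, shape k), which spans both skew signs:
    k < 0 is the classical log-logistic with a lower bound, k > 0 its
    reflection.  Returns (xi, alpha, k).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    j = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((j - 1) / (n - 1) * x) / n
    b2 = np.sum((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * x) / n
    l1 = b0
    l2 = 2 * b1 - b0
    t3 = (6 * b2 - 6 * b1 + b0) / l2
    if not np.isfinite(t3) or not -1 < t3 < 1 or l2 <= 0:
        raise SpeiError(f"L-moments invalid (l2={l2:.4g}, t3={t3:.4g})")
    k = -t3
    if abs(k) < 1e-8:  # logistic limit
        return float(l1), float(l2), 0.0
    g1g2 = gamma_fn(1 + k) * gamma_fn(1 - k)  # = k*pi/sin(k*pi)
    alpha = l2 / g1g2
    xi = l1 - alpha * (1 / k - g1g2 / k)
    if not (np.isfinite(alpha) and alpha > 0 and np.isfinite(xi)):
        raise SpeiError("log-logistic scale/location parameters invalid")
    return float(xi), float(alpha), float(k)


def _loglogistic_cdf(x: np.ndarray, xi: float, alpha: float, k: float) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - xi) / alpha
    if k == 0:
        y = z
    else:
        arg = 1.0 - k * z
        # beyond the support bound: F -> 0 below a lower bound (k < 0),
        # F -> 1 above an upper bound (k > 0)
        outside = -np.inf if k < 0 else np.inf
        y = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)) / k, outside)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-y))


_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308


def standard_normal_quantile(p) -> np.ndarray:
    """Abramowitz-Stegun 26.2.23 rational approximation to the normal quantile."""
    p = np.clip(np.asarray(p, dtype=float), 1e-9, 1 - 1e-9)
    tail = np.minimum(p, 1 - p)
    w = np.sqrt(-2.0 * np.log(tail))
    z = w - (_C0 + _C1 * w + _C2 * w ** 2) / (1 + _D1 * w + _D2 * w ** 2 + _D3 * w ** 3)
    return np.where(p < 0.5, -z, z)


def spei(series: ClimateSeries, scale: int = 3) -> SpeiSeries:
    """SPEI at time scale ``scale`` months; calibration over the full record.

    The k-month water balance ending in each month is standardized per
    calendar month through the fitted log-logistic CDF and the normal
    quantile.  The first k-1 months are undefined.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if "balance" not in series.data.columns:
        series = thornthwaite_pet(series)
    df = series.data
    if len(series.years) < 20:
        raise SpeiError("record shorter than 20 years; calibration not feasible")
    d = df["balance"].to_numpy()
    rolled = pd.Series(d).rolling(scale).sum().to_numpy()
    months = df["month"].to_numpy()
    out = np.full(d.size, np.nan)
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(rolled)
        x = rolled[sel]
        if x.size == 0:
            continue
        if np.std(x) == 0:
            raise SpeiError(f"degenerate water balance (zero variance) in month {m}")
        beta, alpha, gam = _loglogistic_pwm(x)
        out[sel] = standard_normal_quantile(_loglogistic_cdf(x, beta, alpha, gam))
    res = df[["year", "month"]].copy()
    res["spei"] = out
    return SpeiSeries(site_id=series.site_id, scale=scale, data=res)


# ---------------------------------------------------------------------------
# drought classification
# ---------------------------------------------------------------------------

def classify_drought(spei_series: SpeiSeries,
                     thresholds=DEFAULT_DROUGHT_THRESHOLDS) -> DroughtCalendar:
    """Class months by SPEI value: moderate (-1.5, -1], severe (-2, -1.5], extreme <= -2.

    ``thresholds`` are the three breakpoints (moderate, severe, extreme),
    each band half-open on the wet side so the bands partition (-inf, t_mod].
    """
    t_mod, t_sev, t_ext = thresholds
    if not t_ext < t_sev < t_mod < 0:
        raise ValueError("thresholds must be descending and negative")
    df = spei_series.data.dropna(subset=["spei"])
    v = df["spei"].to_numpy()
    severity = np.select(
        [v <= t_ext, v <= t_sev, v <= t_mod],
        ["extreme", "severe", "moderate"], default="")
    keep = severity != ""
    entries = df.loc[keep, ["year", "month"]].copy()
    entries["severity"] = severity[keep]
    return DroughtCalendar(site_id=spei_series.site_id, entries=entries)


def drought_year_summary(calendars) -> dict:
    """Per-site drought-year counts and the cross-site common extreme years.

    ``calendars``: one :class:`DroughtCalendar` or an iterable of them.
    A year counts as severe-or-extreme (extreme) if it contains at least
    one month of that class.
    """
    if isinstance(calendars, DroughtCalendar):
        calendars = [calendars]
    calendars = list(calendars)
    rows = []
    extreme_sets = []
    for cal in calendars:
        sev_ext = cal.severe_or_extreme_years()
        ext = cal.extreme_years()
        extreme_sets.append(set(ext))
        rows.append({"site": cal.site_id,
                     "n_years_severe_or_extreme": len(sev_ext),
                     "n_years_extreme": len(ext),
                     "years_severe_or_extreme": sev_ext,
                     "years_extreme": ext})
    common = sorted(set.intersection(*extreme_sets)) if extreme_sets else []
    return {"per_site": pd.DataFrame(rows), "common_extreme_years": common}
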