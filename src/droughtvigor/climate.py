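"""Monthly climate handling: FAO-56 Penman-Monteith reference
evapotranspiration from reduced station data, annual water balance
(P - PET), seasonal aggregation and Mann-Kendall trend tests with Sen
slopes.

The default PET pathway assumes a station that records only monthly
Tmax, Tmin and precipitation: solar radiation is estimated from the
extraterrestrial flux and the diurnal temperature range (Hargreaves
k_rs = 0.16, interior location), wind speed defaults to 2 m s^-1 and
actual vapour pressure is taken at Tmin. Full inputs can be supplied to
override every estimate.
"""

from __future__ import annotations

import calendar
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, ValidationError

STEFAN_BOLTZMANN = 4.903e-9  # MJ K^-4 m^-2 day^-1
SOLAR_CONSTANT = 0.0820      # MJ m^-2 min^-1

# mid-month representative day of year (non-leap)
_MID_MONTH_DOY = [17, 46, 75, 105, 135, 162, 198, 228, 258, 288, 318, 344]

SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF",
                   3: "MAM", 4: "MAM", 5: "MAM",
                   6: "JJA", 7: "JJA", 8: "JJA",
                   9: "SON", 10: "SON", 11: "SON"}


def saturation_vapour_pressure(t_celsius):
    """Tetens saturation vapour pressure, kPa."""
    t = np.asarray(t_celsius, float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(latitude_deg, day_of_year):
    """Daily extraterrestrial radiation Ra, MJ m^-2 day^-1 (FAO-56)."""
    phi = math.radians(latitude_deg)
    dr = 1 + 0.033 * math.cos(2 * math.pi * day_of_year / 365)
    delta = 0.409 * math.sin(2 * math.pi * day_of_year / 365 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))  # sunset hour angle
    return (24 * 60 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )


def pet_fao56_monthly(year, month, tmax, tmin, latitude_deg, elevation_m,
                      wind_u2=2.0, krs=0.16, ea=None, rs=None):
    """FAO-56 Penman-Monteith reference evapotranspiration, mm month^-1.

    Daily ET0 is computed for the mid-month day and scaled by the number
    of days in the month; soil heat flux is neglected (G = 0), adequate
    at monthly resolution for trend and balance work.
    """
    if not -90 <= latitude_deg <= 90:
        raise ValidationError(f"latitude {latitude_deg} outside [-90, 90]")
    if tmax < tmin:
        raise ValidationError(f"tmax {tmax} < tmin {tmin} in {year}-{month:02d}")
    if not 1 <= month <= 12:
        raise ValidationError(f"month {month} outside 1-12")

    tmean = (tmax + tmin) / 2.0
    es_tmax = float(saturation_vapour_pressure(tmax))
    es_tmin = float(saturation_vapour_pressure(tmin))
    es = (es_tmax + es_tmin) / 2.0
    if ea is None:
        ea = es_tmin  # reduced-data estimate: dewpoint ~ Tmin
    ea = min(ea, es)

    delta = 4098 * float(saturation_vapour_pressure(tmean)) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293 - 0.0065 * elevation_m) / 293) ** 5.26
    gamma = 0.000665 * pressure

    doy = _MID_MONTH_DOY[month - 1]
    ra = extraterrestrial_radiation(latitude_deg, doy)
    if rs is None:
        rs = krs * math.sqrt(max(tmax - tmin, 0.0)) * ra
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = (1 - 0.23) * rs
    rel = min(rs / rso, 1.0) if rso > 0 else 1.0
    rnl = STEFAN_BOLTZMANN * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2) \
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0))) * (1.35 * rel - 0.35)
    rn = rns - rnl

    et0 = (0.408 * delta * rn
           + gamma * (900 / (tmean + 273)) * wind_u2 * (es - ea)) \
        / (delta + gamma * (1 + 0.34 * wind_u2))
    et0 = max(et0, 0.0)
    return et0 * calendar.monthrange(year, month)[1]


def validate_monthly(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a monthly climate table (year, month, tmax, tmin, precip)."""
    required = {"year", "month", "tmax", "tmin", "precip"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing climate columns: {sorted(missing)}")
    if (df["tmax"] < df["tmin"]).any():
        bad = df[df["tmax"] < df["tmin"]].iloc[0]
        raise ValidationError(f"tmax < tmin at {int(bad.year)}-{int(bad.month):02d}")
    if (df["precip"] < 0).any():
        raise ValidationError("negative precipitation")
    if not df["month"].between(1, 12).all():
        raise ValidationError("month outside 1-12")
    return df


@dataclass
class WaterBalanceYear:
    year: int
    precip_total: float
    pet_total: float

    @property
    def balance(self) -> float:
        return self.precip_total - self.pet_total


def annual_water_balance(df: pd.DataFrame, latitude_deg, elevation_m,
                         **pet_kwargs) -> pd.DataFrame:
    """Per-year precipitation, PET and climatic water balance P - PET.

    Years with fewer than 12 months are excluded with a warning. The
    returned frame is sorted by year and carries a ``rank`` column
    (1 = driest balance), so the most extreme drought year is
    ``df.loc[df['rank'] == 1]``.
    """
    df = validate_monthly(df)
    rows = []
    for year, g in df.groupby("year"):
        if len(g) < 12 or set(g["month"]) != set(range(1, 13)):
            warnings.warn(f"year {year} incomplete; excluded from water balance")
            continue
        pet = sum(
            pet_fao56_monthly(int(r.year), int(r.month), r.tmax, r.tmin,
                              latitude_deg, elevation_m, **pet_kwargs)
            for r in g.itertuples()
        )
        rows.append({"year": int(year), "precip_total": float(g["precip"].sum()),
                     "pet_total": float(pet)})
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    out["balance"] = out["precip_total"] - out["pet_total"]
    out["rank"] = out["balance"].rank(method="min").astype(int)
    return out


def driest_year(balance: pd.DataFrame) -> int:
    """Year with the most negative climatic water balance."""
    return int(balance.loc[balance["balance"].idxmin(), "year"])


@dataclass
class MannKendallResult:
    s: int
    var_s: float
    z: float
    p: float
    sen_slope: float
    n: int

    @property
    def trend(self) -> str:
        if self.p >= 0.05:
            return "none"
        return "increasing" if self.s > 0 else "decreasing"


def _exact_s_tail_p(n: int, s_obs: int) -> float:
    """Exact two-sided P(|S| >= |s_obs|) for tie-free series of length n.

    S = n(n-1)/2 - 2 * inversions, so the null distribution follows the
    Mahonian inversion counts, built by dynamic programming.
    """
    max_inv = n * (n - 1) // 2
    counts = np.zeros(max_inv + 1, dtype=float)
    counts[0] = 1.0
    for k in range(2, n + 1):  # insert the k-th element: adds 0..k-1 inversions
        new = np.zeros_like(counts)
        cum = np.concatenate([[0.0], np.cumsum(counts)])
        for inv in range(max_inv + 1):
            lo = max(inv - (k - 1), 0)
            new[inv] = cum[inv + 1] - cum[lo]
        counts = new
    s_values = max_inv - 2 * np.arange(max_inv + 1)
    mask = np.abs(s_values) >= abs(s_obs)
    return float(counts[mask].sum() / counts.sum())


def mann_kendall(series, exact_max_n: int = 10) -> MannKendallResult:
    """Mann-Kendall trend test with tie-corrected variance and Sen slope.

    S = sum over i<j of sign(x_j - x_i). The z score always uses the
    +-1 continuity-corrected normal approximation; the p-value is exact
    (inversion-count distribution) for tie-free series up to
    ``exact_max_n`` and the normal approximation otherwise. The Sen
    slope is the median of all pairwise slopes.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"mann_kendall needs n >= 4, got {n}")
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    if len(ties) == 0 and n <= exact_max_n:
        p = _exact_s_tail_p(n, s)
    else:
        p = 2 * (1 - sps.norm.cdf(abs(z)))
    idx_i, idx_j = np.triu_indices(n, k=1)
    slopes = (x[idx_j] - x[idx_i]) / (idx_j - idx_i)
    return MannKendallResult(s, float(var_s), float(z), float(p),
                             float(np.median(slopes)), n)


def seasonal_aggregate(df: pd.DataFrame) -> pd.DataFrame:
    """Season x year table: temperature means, precipitation sums.

    December is assigned to the following year's DJF. Seasons with fewer
    than three months are flagged ``complete=False`` (exclude them from
    trend tests).
    """
    df = validate_monthly(df).copy()
    df["season"] = df["month"].map(SEASON_OF_MONTH)
    df["season_year"] = np.where(df["month"] == 12, df["year"] + 1, df["year"])
    rows = []
    for (sy, season), g in df.groupby(["season_year", "season"]):
        rows.append({
            "season_year": int(sy), "season": season,
            "tmax_mean": float(g["tmax"].mean()),
            "tmin_mean": float(g["tmin"].mean()),
            "tmean": float(((g["tmax"] + g["tmin"]) / 2).mean()),
            "precip_sum": float(g["precip"].sum()),
            "n_months": int(len(g)),
            "complete": len(g) == 3,
        })
    return pd.DataFrame(rows).sort_values(["season_year", "season"]).reset_index(drop=True)


def seasonal_trends(seasonal: pd.DataFrame, variable="tmean") -> pd.DataFrame:
    """Mann-Kendall trend per season for one seasonal variable.

    Emits both the Sen slope and an OLS slope per decade so either trend
    summary can be quoted.
    """
    rows = []
    for season, g in seasonal[seasonal["complete"]].groupby("season"):
        g = g.sort_values("season_year")
        if len(g) < 4:
            continue
        mk = mann_kendall(g[variable].to_numpy())
        ols = sps.linregress(g["season_year"], g[variable])
        rows.append({"season": season, "variable": variable, "n": mk.n,
                     "s": mk.s, "z": mk.z, "p": mk.p,
                     "sen_slope_per_decade": mk.sen_slope * 10,
                     "ols_slope_per_decade": float(ols.slope * 10)})
    return pd.DataFrame(rows)
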