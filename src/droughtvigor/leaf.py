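"""Leaf morphometrics and minimum leaf conductance (gmin).

gmin — the residual vapour conductance of a needle once stomata are
fully closed — is estimated from the mass loss of desiccating needles
held in darkness at ~25 degC over silica gel (relative humidity ~0).
After an initial stomatal phase the mass-time curve becomes linear
(cuticular phase); the slope of that phase, normalised by leaf area and
the mole-fraction vapour gradient, is gmin:

    gmin = (-dm/dt / M_w) / (A * dw),   dw = es(T) * (1 - RH) / P

with M_w = 18.015 g mol^-1 and es from the Tetens formula. Reported in
mmol m^-2 s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

import pandas as pd

from .climate import saturation_vapour_pressure
from .exceptions import DomainError, InsufficientDataError, UndefinedCorrelationError, ValidationError
from .stats import welch_t

MOLAR_MASS_WATER = 18.015     # g mol^-1
STANDARD_PRESSURE = 101.325   # kPa
# hemicylindrical projected -> total surface conversion for pine needles
HEMICYLINDRICAL_FACTOR = (np.pi + 2) / 2


def lma(dry_mass_g, area_cm2):
    """Leaf mass per area, g m^-2, from dry mass (g) and area (cm^2)."""
    area_cm2 = np.asarray(area_cm2, float)
    if np.any(area_cm2 <= 0):
        raise DomainError("leaf area must be > 0")
    out = np.asarray(dry_mass_g, float) / (area_cm2 * 1e-4)
    return float(out) if out.ndim == 0 else out


def total_area_from_projected(projected_area, factor=HEMICYLINDRICAL_FACTOR):
    """Convert projected needle area to total transpiring surface."""
    return projected_area * factor


def mole_fraction_gradient(temperature_c, relative_humidity=0.0,
                           pressure_kpa=STANDARD_PRESSURE):
    """Leaf-to-air water vapour mole-fraction difference (dimensionless)."""
    if pressure_kpa <= 0:
        raise DomainError("pressure must be > 0")
    es = float(saturation_vapour_pressure(temperature_c))
    return es * (1.0 - relative_humidity) / pressure_kpa


@dataclass
class DesiccationSeries:
    """Mass-time record of needles drying in a controlled chamber."""

    tree_id: str
    times: np.ndarray        # s, strictly increasing
    masses: np.ndarray       # g
    leaf_area: float         # m^2 (basis recorded by the caller)
    chamber_temperature: float = 25.0  # degC
    relative_humidity: float = 0.0
    pressure: float = STANDARD_PRESSURE  # kPa

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.masses = np.asarray(self.masses, float)
        if len(self.times) != len(self.masses):
            raise ValidationError("times and masses differ in length")
        if len(self.times) < 5:
            raise ValidationError("desiccation series needs >= 5 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be > 0")
        if self.leaf_area <= 0:
            raise DomainError("leaf_area must be > 0")


@dataclass
class GminFit:
    """gmin estimate plus the linear-phase diagnostics behind it."""

    tree_id: str
    gmin: float              # mmol m^-2 s^-1
    slope: float             # g s^-1 over the cuticular phase
    phase_start_index: int
    n_phase_points: int
    success: bool = True
    message: str = "ok"
    log: list = field(default_factory=list)


def _quadratic_term_p(t, m):
    """p-value of the quadratic coefficient in m ~ t + t^2 (H0: linear)."""
    x = np.column_stack([np.ones_like(t), t, t * t])
    coef, res, rank, _ = np.linalg.lstsq(x, m, rcond=None)
    n, k = len(t), 3
    if n <= k:
        return 1.0
    rss = float(res[0]) if len(res) else float(np.sum((m - x @ coef) ** 2))
    fitted_range = float(m.max() - m.min()) or 1.0
    if rss < (1e-12 * fitted_range) ** 2 * n:
        return 1.0  # numerically perfect fit: no detectable curvature
    sigma2 = rss / (n - k)
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[2, 2])
    if se == 0:
        return 0.0
    tstat = coef[2] / se
    return float(2 * (1 - sps.t.cdf(abs(tstat), n - k)))


def fit_gmin(series: DesiccationSeries, alpha=0.05, min_points=5,
             noise_tolerance=0.002) -> GminFit:
    """Estimate gmin from one desiccation series.

    Linear-phase selection: among terminal windows [i, end) with at
    least ``min_points`` points, keep the longest whose quadratic term
    is non-significant at ``alpha`` — i.e. the longest stretch at the
    dry end of the record indistinguishable from a straight line. The
    slope over that window (ordinary least squares), converted to a
    molar flux and normalised by area and vapour gradient, is gmin.

    Returns ``success=False`` with diagnostics when no linear phase is
    detectable; warns when masses increase by more than
    ``noise_tolerance`` g between consecutive readings.
    """
    t, m = series.times, series.masses
    increases = np.diff(m)
    if np.any(increases > noise_tolerance):
        warnings.warn(
            f"series {series.tree_id}: mass increases beyond noise tolerance")
    n = len(t)
    log = []
    chosen = None
    for start in range(0, n - min_points + 1):
        p = _quadratic_term_p(t[start:], m[start:])
        log.append(f"window[{start}:]: quadratic p={p:.3g}")
        if p >= alpha:
            chosen = start
            break  # first (longest) admissible terminal window
    if chosen is None:
        return GminFit(series.tree_id, float("nan"), float("nan"), -1, 0,
                       success=False,
                       message="no linear (cuticular) phase detected", log=log)
    tw, mw = t[chosen:], m[chosen:]
    slope = float(np.polyfit(tw, mw, 1)[0])
    dw = mole_fraction_gradient(series.chamber_temperature,
                                series.relative_humidity, series.pressure)
    flux_mol = max(-slope, 0.0) / MOLAR_MASS_WATER           # mol s^-1
    gmin = flux_mol / (series.leaf_area * dw) * 1000.0       # mmol m^-2 s^-1
    return GminFit(series.tree_id, gmin, slope, chosen, len(tw), log=log)


def gmin_to_mass_slope(gmin_mmol, leaf_area, temperature_c=25.0,
                       relative_humidity=0.0, pressure_kpa=STANDARD_PRESSURE):
    """Inverse of the gmin formula: mass-loss slope (g s^-1, negative)."""
    if leaf_area <= 0:
        raise DomainError("leaf_area must be > 0")
    dw = mole_fraction_gradient(temperature_c, relative_humidity, pressure_kpa)
    return -(gmin_mmol / 1000.0) * leaf_area * dw * MOLAR_MASS_WATER


def summarize_water_potentials(records: pd.DataFrame) -> dict:
    """Class x date x time-of-day water-potential summary with Welch flags.

    ``records`` columns: tree_id, vigour_class, date, time_of_day
    ('predawn'|'midday'), psi (MPa, <= 0). Tree-dates where predawn is
    more negative than midday are physiologically implausible and
    flagged.
    """
    required = {"tree_id", "vigour_class", "date", "time_of_day", "psi"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    if (records["psi"] > 0).any():
        raise ValidationError("water potentials must be <= 0 MPa")

    flagged = []
    wide = records.pivot_table(index=["tree_id", "date"], columns="time_of_day",
                               values="psi", aggfunc="mean")
    if {"predawn", "midday"} <= set(wide.columns):
        bad = wide[wide["predawn"] < wide["midday"]]
        flagged = [tuple(map(str, idx)) for idx in bad.index]

    rows = []
    tests = []
    for (date, tod), g in records.groupby(["date", "time_of_day"]):
        by_class = {}
        for cls, gc in g.groupby("vigour_class"):
            vals = gc["psi"].to_numpy()
            rows.append({"date": str(date), "time_of_day": tod,
                         "vigour_class": cls, "mean": float(vals.mean()),
                         "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                         if len(vals) > 1 else float("nan"),
                         "n": len(vals)})
            by_class[cls] = vals
        if len(by_class) == 2 and all(len(v) >= 2 for v in by_class.values()):
            (c1, v1), (c2, v2) = sorted(by_class.items())
            tstat, _, p = welch_t(v1, v2)
            tests.append({"date": str(date), "time_of_day": tod,
                          "classes": f"{c1} vs {c2}", "t": tstat, "p": p,
                          "significant": p < 0.05})
    return {"summary": pd.DataFrame(rows), "tests": pd.DataFrame(tests),
            "flagged_tree_dates": flagged}


def correlate_traits(x, y):
    """Pearson correlation with two-sided p between per-tree trait values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need >= 3 paired values")
    if x.var() == 0 or y.var() == 0:
        raise UndefinedCorrelationError("zero variance in one variable")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
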