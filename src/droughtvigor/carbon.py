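"""Wood delta13C -> discrimination -> Ci -> intrinsic water-use
efficiency (iWUE).

The chain uses the simple Farquhar discrimination model:

    D13C = (d13C_a - d13C_w) / (1 + d13C_w / 1000)        [permil]
    Ci   = Ca * (D13C - a) / (b - a)                      [umol mol^-1]
    iWUE = Ca * (1 - Ci / Ca) * 0.625                     [umol mol^-1]

with a = 4.4 permil (diffusive fractionation), b = 27.0 permil (Rubisco
fractionation) and 0.625 the ratio of CO2 to H2O stomatal conductances.
The composition is equivalent to the closed form
iWUE = 0.625 * Ca * (b - D13C) / (b - a).

A packaged atmospheric reference table supplies Ca and d13C_a per year;
it is a synthetic approximation of the published global records (Mauna
Loa / ice-core CO2, atmospheric d13C decline) and can be replaced by
any table with columns year, Ca, d13C_atm.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .stats import welch_t

FRACTIONATION_A = 4.4    # permil, boundary layer + stomata diffusion
FRACTIONATION_B = 27.0   # permil, Rubisco carboxylation
CONDUCTANCE_RATIO = 0.625  # g(CO2) / g(H2O)

_ATMOSPHERE_FILE = "atmospheric_co2_d13c_synthetic.csv"


def discrimination(d13c_wood, d13c_atm):
    """Photosynthetic 13C discrimination D13C (permil)."""
    w = np.asarray(d13c_wood, float)
    a = np.asarray(d13c_atm, float)
    denom = 1.0 + w / 1000.0
    if np.any(denom <= 0):
        raise DomainError("d13C_wood must exceed -1000 permil")
    out = (a - w) / denom
    return float(out) if out.ndim == 0 else out


def d13c_wood_from_discrimination(delta13c, d13c_atm):
    """Invert the discrimination formula (round-trip identity)."""
    delta13c = np.asarray(delta13c, float)
    out = (np.asarray(d13c_atm, float) - delta13c) / (1.0 + delta13c / 1000.0)
    return float(out) if out.ndim == 0 else out


def ci_from_discrimination(delta13c, ca, a=FRACTIONATION_A, b=FRACTIONATION_B):
    """Intercellular CO2 from discrimination via the simple model.

    Values outside [0, Ca] are physically implausible (wood-chemistry
    outliers) and trigger a warning, never an exception; the caller
    decides the clipping policy.
    """
    if b <= a:
        raise DomainError("need b > a")
    ca_arr = np.asarray(ca, float)
    if np.any(ca_arr <= 0):
        raise DomainError("Ca must be > 0")
    ci = ca_arr * (np.asarray(delta13c, float) - a) / (b - a)
    if np.any((ci < 0) | (ci > ca_arr)):
        warnings.warn("Ci outside [0, Ca] for some records")
    return float(ci) if ci.ndim == 0 else ci


def iwue(ci, ca):
    """Intrinsic water-use efficiency, umol H2O mol^-1 CO2."""
    ca_arr = np.asarray(ca, float)
    if np.any(ca_arr <= 0):
        raise DomainError("Ca must be > 0")
    out = ca_arr * (1.0 - np.asarray(ci, float) / ca_arr) * CONDUCTANCE_RATIO
    return float(out) if out.ndim == 0 else out


def iwue_from_d13c(d13c_wood, d13c_atm, ca,
                   a=FRACTIONATION_A, b=FRACTIONATION_B):
    """Full chain d13C_w -> D13C -> Ci -> iWUE."""
    delta = discrimination(d13c_wood, d13c_atm)
    return iwue(ci_from_discrimination(delta, ca, a, b), ca)


def load_atmospheric_reference() -> pd.DataFrame:
    """Packaged yearly Ca (umol mol^-1) and atmospheric d13C (permil)."""
    with resources.files("droughtvigor.data").joinpath(_ATMOSPHERE_FILE).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return validate_atmospheric_reference(df)


def validate_atmospheric_reference(df: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "Ca", "d13C_atm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"atmospheric table missing: {sorted(missing)}")
    if df["year"].duplicated().any():
        raise ValidationError("duplicate years in atmospheric table")
    if (df["Ca"] <= 0).any():
        raise ValidationError("Ca must be > 0")
    return df


def wood_carbon_chain(records: pd.DataFrame,
                      atmosphere: pd.DataFrame | None = None) -> pd.DataFrame:
    """Annotate per-ring d13C records with D13C, Ci and iWUE.

    ``records`` columns: tree_id, year, d13C_wood. Wood less depleted
    than the contemporaneous atmosphere is flagged with a warning
    (physically implausible for plant tissue).
    """
    required = {"tree_id", "year", "d13C_wood"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"carbon table missing: {sorted(missing)}")
    atmosphere = validate_atmospheric_reference(
        atmosphere if atmosphere is not None else load_atmospheric_reference())
    out = records.merge(atmosphere, on="year", how="left")
    if out["Ca"].isna().any():
        years = sorted(out.loc[out["Ca"].isna(), "year"].unique())
        raise ValidationError(f"atmospheric reference missing years: {years}")
    if (out["d13C_wood"] >= out["d13C_atm"]).any():
        warnings.warn("wood d13C >= atmospheric d13C for some rings")
    out["delta13C"] = discrimination(out["d13C_wood"].to_numpy(),
                                     out["d13C_atm"].to_numpy())
    out["Ci"] = ci_from_discrimination(out["delta13C"].to_numpy(),
                                       out["Ca"].to_numpy())
    out["iwue"] = iwue(out["Ci"].to_numpy(), out["Ca"].to_numpy())
    return out


def iwue_series_comparison(d_records: pd.DataFrame, nd_records: pd.DataFrame,
                           atmosphere: pd.DataFrame | None = None,
                           alpha=0.05) -> dict:
    """Per-year class iWUE means with Welch-t flags and significant windows.

    Input frames are per-ring d13C tables (tree_id, year, d13C_wood),
    one per vigour class. Years lacking two trees in either class are
    reported untested.
    """
    chains = {"D": wood_carbon_chain(d_records, atmosphere),
              "ND": wood_carbon_chain(nd_records, atmosphere)}
    rows = []
    years = sorted(set(chains["D"]["year"]) | set(chains["ND"]["year"]))
    for year in years:
        row = {"year": int(year)}
        vals = {}
        for cls, chain in chains.items():
            v = chain.loc[chain["year"] == year, "iwue"].to_numpy()
            row[f"mean_{cls}"] = float(v.mean()) if len(v) else float("nan")
            row[f"se_{cls}"] = (float(v.std(ddof=1) / np.sqrt(len(v)))
                                if len(v) > 1 else float("nan"))
            row[f"n_{cls}"] = len(v)
            vals[cls] = v
        if all(len(v) >= 2 for v in vals.values()):
            t, _, p = welch_t(vals["D"], vals["ND"])
            row.update(t=t, p=p, tested=True, significant=p < alpha)
        else:
            row.update(t=float("nan"), p=float("nan"), tested=False,
                       significant=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    windows = significant_windows(table)
    return {"table": table, "significant_windows": windows}


def significant_windows(table: pd.DataFrame, year_col="year",
                        flag_col="significant") -> list:
    """Contiguous runs of significant years as (start, end) tuples."""
    runs = []
    current = None
    for _, r in table.sort_values(year_col).iterrows():
        if r[flag_col]:
            y = int(r[year_col])
            if current and y == current[1] + 1:
                current = (current[0], y)
            else:
                if current:
                    runs.append(current)
                current = (y, y)
        else:
            if current:
                runs.append(current)
                current = None
    if current:
        runs.append(current)
    return runs
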