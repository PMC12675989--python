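"""Wood and bordered-pit anatomy metrics.

Tracheid level: radial lumen diameter, double cell-wall thickness and
the thickness-to-span ratio (double wall / lumen)^2, summarised per
tree-ring. Pit level: from the aperture (Da), torus (Dt) and membrane
(Dm) diameters,

    torus overlap     = (Dt - Da) / Dt
    margo flexibility = (Dm - Dt) / Dm
    valve effect      = torus overlap x margo flexibility

computed per pit, then averaged per tree and period. Pits whose
aperture exceeds the torus (Da > Dt) yield a negative overlap; they are
retained and flagged rather than clipped, since clipping would bias
class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError
from .stats import welch_t

# six 5-year earlywood windows analysed in stem cores
DEFAULT_PIT_PERIODS = [(1970, 1974), (1980, 1984), (1990, 1994),
                       (2000, 2004), (2010, 2014), (2017, 2021)]
PIT_METRIC_NAMES = ["torus_overlap", "margo_flexibility", "valve_effect"]


@dataclass
class PitMetrics:
    torus_overlap: float
    margo_flexibility: float
    valve_effect: float
    aperture_exceeds_torus: bool = False


def pit_metrics(da, dt, dm) -> PitMetrics:
    """Sealing metrics of one bordered pit from its three diameters (um)."""
    if dt <= 0 or dm <= 0:
        raise DomainError("Dt and Dm must be > 0")
    if da <= 0:
        raise DomainError("Da must be > 0")
    overlap = (dt - da) / dt
    flexibility = (dm - dt) / dm
    return PitMetrics(overlap, flexibility, overlap * flexibility,
                      aperture_exceeds_torus=da > dt)


def validate_pit_table(df: pd.DataFrame) -> pd.DataFrame:
    """Reject pit rows violating Da <= Dm or Dt <= Dm or non-positive diameters."""
    for col in ("Da", "Dt", "Dm"):
        if col not in df.columns:
            raise ValidationError(f"pit table missing column {col!r}")
        if (df[col] <= 0).any():
            raise ValidationError(f"non-positive {col} in pit table")
    if (df["Da"] > df["Dm"]).any() or (df["Dt"] > df["Dm"]).any():
        raise ValidationError("pit rows with Da > Dm or Dt > Dm rejected")
    return df


def pit_metrics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-pit metrics appended to a validated pit table."""
    df = validate_pit_table(df).copy()
    df["torus_overlap"] = (df["Dt"] - df["Da"]) / df["Dt"]
    df["margo_flexibility"] = (df["Dm"] - df["Dt"]) / df["Dm"]
    df["valve_effect"] = df["torus_overlap"] * df["margo_flexibility"]
    df["aperture_exceeds_torus"] = df["Da"] > df["Dt"]
    return df


def pit_tree_means(df: pd.DataFrame, by=("tree_id",)) -> pd.DataFrame:
    """Average per-pit metrics up to the tree (or tree-period) level."""
    metrics = pit_metrics_table(df)
    cols = PIT_METRIC_NAMES + ["Da", "Dt", "Dm"]
    return metrics.groupby(list(by))[cols].mean().reset_index()


def thickness_to_span(double_wall, lumen):
    """Square of the double-wall-to-lumen ratio (Hacke et al. convention)."""
    lumen = np.asarray(lumen, float)
    if np.any(lumen <= 0):
        raise DomainError("lumen diameter must be > 0")
    out = (np.asarray(double_wall, float) / lumen) ** 2
    return float(out) if out.ndim == 0 else out


def ring_anatomy_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per tree-year anatomy means from tracheid measurements.

    Expects columns tree_id, year, lumen_diameter, double_wall_thickness.
    The thickness-to-span ratio is computed per tracheid *before*
    averaging (the mean of per-tracheid ratios, not the ratio of means).
    """
    required = {"tree_id", "year", "lumen_diameter", "double_wall_thickness"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"tracheid table missing columns: {sorted(missing)}")
    if (df["lumen_diameter"] <= 0).any() or (df["double_wall_thickness"] <= 0).any():
        raise ValidationError("non-positive tracheid measurement")
    work = df.copy()
    work["thickness_to_span"] = thickness_to_span(
        work["double_wall_thickness"].to_numpy(), work["lumen_diameter"].to_numpy())
    out = work.groupby(["tree_id", "year"]).agg(
        lumen_diameter=("lumen_diameter", "mean"),
        double_wall_thickness=("double_wall_thickness", "mean"),
        thickness_to_span=("thickness_to_span", "mean"),
        n_tracheids=("lumen_diameter", "size"),
    ).reset_index()
    return out


def _period_label(period):
    return f"{period[0]}-{period[1]}"


def compare_pit_periods(d_pits: pd.DataFrame, nd_pits: pd.DataFrame,
                        periods=None) -> pd.DataFrame:
    """Welch t per period and metric on tree-level pit means.

    Tests use one value per tree (the mean of its ~10 pits in the
    period) to avoid pseudo-replication. Pit tables need columns
    tree_id, year, Da, Dt, Dm.
    """
    periods = periods or DEFAULT_PIT_PERIODS
    rows = []
    for period in periods:
        lo, hi = period
        label = _period_label(period)
        per_class = {}
        for cls, table in (("D", d_pits), ("ND", nd_pits)):
            sel = table[(table["year"] >= lo) & (table["year"] <= hi)]
            if sel.empty:
                continue
            per_class[cls] = pit_tree_means(sel)
        if set(per_class) != {"D", "ND"}:
            raise ValidationError(f"period {label} missing a class")
        for metric in PIT_METRIC_NAMES:
            d_vals = per_class["D"][metric].to_numpy()
            nd_vals = per_class["ND"][metric].to_numpy()
            if len(d_vals) < 2 or len(nd_vals) < 2:
                raise ValidationError(
                    f"period {label}: need >= 2 trees per class")
            t, dof, p = welch_t(d_vals, nd_vals)
            rows.append({"period": label, "metric": metric,
                         "mean_D": float(d_vals.mean()),
                         "mean_ND": float(nd_vals.mean()),
                         "n_D": len(d_vals), "n_ND": len(nd_vals),
                         "t": t, "df": dof, "p": p,
                         "significant": p < 0.05})
    return pd.DataFrame(rows)
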