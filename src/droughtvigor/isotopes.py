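"""Dual water-isotope (d18O, d2H) source analysis.

Samples carry a provenance class (xylem of declining / non-declining
pines or oaks, two soil depths, well, river). The soil evaporation line
is an OLS fit of d2H on d18O through the soil and recharge (well,
river) samples of one sampling date; xylem samples are located by their
offset from that line and by their position along the enrichment axis
(more negative compositions indicate deeper, less evaporated water).
No mixing model is applied — depth inference stays qualitative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DomainError, InsufficientDataError, ValidationError
from .stats import anova_oneway, significance_letters, welch_t

SOURCE_CLASSES = frozenset({
    "xylem-D", "xylem-ND", "xylem-oak",
    "soil-0-15", "soil-15-30", "well", "river",
})
EVAPORATION_LINE_CLASSES = ("soil-0-15", "soil-15-30", "well", "river")
XYLEM_CLASSES = ("xylem-D", "xylem-ND", "xylem-oak")


@dataclass
class IsotopeLine:
    """d2H = intercept + slope * d18O."""

    slope: float        # permil / permil
    intercept: float    # permil
    r_squared: float
    n: int
    kind: str = "evaporation"  # or "meteoric"

    def predict(self, d18o):
        return self.intercept + self.slope * np.asarray(d18o, float)


# global meteoric water line of the study region (intercept 8.06, slope 7.77)
GLOBAL_METEORIC_LINE = IsotopeLine(slope=7.77, intercept=8.06,
                                   r_squared=0.99, n=0, kind="meteoric")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "date", "source_class", "d18O", "d2H"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"isotope table missing columns: {sorted(missing)}")
    unknown = set(df["source_class"]) - SOURCE_CLASSES
    if unknown:
        raise ValidationError(f"unknown source classes: {sorted(unknown)}")
    if df[["d18O", "d2H"]].isna().any().any():
        raise ValidationError("isotope pairs must be complete")
    return df


def fit_isotope_line(d18o, d2h, kind="evaporation") -> IsotopeLine:
    """Ordinary least squares of d2H on d18O."""
    x = np.asarray(d18o, float)
    y = np.asarray(d2h, float)
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 samples to fit a line")
    if np.ptp(x) == 0:
        raise DomainError("all d18O identical; line is vertical")
    res = sps.linregress(x, y)
    r2 = 1.0 if len(x) == 2 else float(res.rvalue ** 2)
    return IsotopeLine(float(res.slope), float(res.intercept), r2, len(x), kind)


def evaporation_line(samples: pd.DataFrame, date) -> IsotopeLine:
    """Soil evaporation line for one sampling date (soil + well + river)."""
    df = validate_samples(samples)
    sel = df[(df["date"] == date) &
             df["source_class"].isin(EVAPORATION_LINE_CLASSES)]
    if sel.empty:
        raise InsufficientDataError(f"no soil/recharge samples on {date}")
    return fit_isotope_line(sel["d18O"], sel["d2H"], kind="evaporation")


def line_offset(d18o, d2h, line: IsotopeLine):
    """Signed d2H distance of sample(s) from a reference line (permil)."""
    out = np.asarray(d2h, float) - line.predict(d18o)
    return float(out) if out.ndim == 0 else out


def groundwater_reference(samples: pd.DataFrame, date=None) -> dict:
    """Mean isotopic composition of the recharge pool (well + river)."""
    df = validate_samples(samples)
    sel = df[df["source_class"].isin(("well", "river"))]
    if date is not None:
        sel = sel[sel["date"] == date]
    if sel.empty:
        raise InsufficientDataError("no well/river samples")
    return {"d18O": float(sel["d18O"].mean()), "d2H": float(sel["d2H"].mean()),
            "n": int(len(sel))}


def compare_depth_signature(samples: pd.DataFrame, date,
                            groups=XYLEM_CLASSES) -> dict:
    """Per-class isotope summary with one-way ANOVA and Welch-t letters.

    Compares the xylem classes on one date for each isotope. Classes
    with a single sample are excluded from testing (with a warning) but
    still summarised. The qualitative depth ordering — more negative
    composition, deeper water — is emitted as an annotation only.
    """
    df = validate_samples(samples)
    sel = df[(df["date"] == date) & df["source_class"].isin(groups)]
    out = {"date": str(date), "isotopes": {}}
    for iso in ("d18O", "d2H"):
        summary = {}
        testable = {}
        for cls, g in sel.groupby("source_class"):
            vals = g[iso].to_numpy()
            summary[cls] = {"mean": float(vals.mean()),
                            "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                            if len(vals) > 1 else float("nan"),
                            "n": len(vals)}
            if len(vals) >= 2:
                testable[cls] = vals
            else:
                warnings.warn(f"class {cls} has one sample on {date}; "
                              "excluded from tests")
        if len(testable) >= 2:
            f, p = anova_oneway(list(testable.values()))
            pair_p = {}
            for a, b in itertools.combinations(sorted(testable), 2):
                _, _, pw = welch_t(testable[a], testable[b])
                pair_p[frozenset((a, b))] = pw
            letters = significance_letters(sorted(testable), pair_p)
        else:
            f, p, letters = float("nan"), float("nan"), {}
        order = sorted(summary, key=lambda c: summary[c]["mean"])
        out["isotopes"][iso] = {
            "summary": summary, "anova_f": f, "anova_p": p,
            "letters": letters,
            "depth_ordering_most_negative_first": order,
        }
    return out


def seasonal_shift(samples_spring: pd.DataFrame,
                   samples_late_summer: pd.DataFrame,
                   groups=XYLEM_CLASSES) -> pd.DataFrame:
    """Late-summer minus spring class means for both isotopes.

    Standard errors combine by quadrature (the two seasons are
    independent samples). Classes missing a season are omitted with a
    warning.
    """
    spring = validate_samples(samples_spring)
    summer = validate_samples(samples_late_summer)
    rows = []
    for cls in groups:
        a = spring[spring["source_class"] == cls]
        b = summer[summer["source_class"] == cls]
        if a.empty or b.empty:
            warnings.warn(f"class {cls} missing a season; omitted")
            continue
        row = {"source_class": cls}
        for iso in ("d18O", "d2H"):
            va, vb = a[iso].to_numpy(), b[iso].to_numpy()
            se_a = va.std(ddof=1) / np.sqrt(len(va)) if len(va) > 1 else 0.0
            se_b = vb.std(ddof=1) / np.sqrt(len(vb)) if len(vb) > 1 else 0.0
            row[f"delta_{iso}"] = float(vb.mean() - va.mean())
            row[f"se_{iso}"] = float(np.hypot(se_a, se_b))
        rows.append(row)
    return pd.DataFrame(rows)
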