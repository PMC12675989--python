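"""Xylem hydraulics: percent loss of conductance, sigmoid vulnerability
curves (Pammenter & Vander Willigen form) with P50/P12/P88 extraction,
native embolism fractions, and hydraulic safety margins.

The vulnerability model is

    PLC(psi) = 100 / (1 + exp((s / 25) * (psi - P50)))

with P50 the xylem pressure (MPa, negative) at 50 % loss of conductance
and s the slope of the curve at P50 in % MPa^-1. Any other threshold
Px follows analytically: psi_x = P50 + (25 / s) * ln(100 / x - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateCurveError, DomainError, ValidationError

REFERENCE_PRESSURE = -0.5  # MPa; low-tension point used as Kmax
PLC_MORTALITY_THRESHOLD = 50.0  # % — conventional lethal PLC for conifers


def plc(ks, kmax):
    """Percent loss of conductance: 100 * (1 - Ks / Kmax), clipped to [0, 100].

    Warns when Ks exceeds Kmax (apparent negative embolism, e.g. flow
    measurement noise) before clipping.
    """
    ks = np.asarray(ks, float)
    if np.any(np.asarray(kmax, float) <= 0):
        raise DomainError("kmax must be > 0")
    if np.any(ks < 0):
        raise DomainError("ks must be >= 0")
    raw = 100.0 * (1.0 - ks / kmax)
    if np.any(raw < 0):
        warnings.warn("Ks > Kmax for some points; PLC clipped to 0")
    out = np.clip(raw, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def sigmoid_plc(pressure, p50, slope):
    """Sigmoid PLC at xylem pressure(s) in MPa."""
    pressure = np.asarray(pressure, float)
    out = 100.0 / (1.0 + np.exp(np.clip((slope / 25.0) * (pressure - p50), -700, 700)))
    return float(out) if out.ndim == 0 else out


def pressure_at_plc(plc_percent, p50, slope):
    """Invert the sigmoid: xylem pressure at a given PLC (0 < plc < 100)."""
    if not 0 < plc_percent < 100:
        raise DomainError("plc_percent must lie strictly in (0, 100)")
    return p50 + (25.0 / slope) * np.log(100.0 / plc_percent - 1.0)


@dataclass
class VulnerabilityCurve:
    """Pressure-PLC points for one sample.

    Build from raw conductances with :meth:`from_conductance`; the mean
    conductance of all points at or above the -0.5 MPa reference tension
    serves as Kmax.
    """

    tree_id: str
    pressures: np.ndarray   # MPa, <= 0
    plc: np.ndarray         # %
    kmax: float | None = None

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, float)
        self.plc = np.asarray(self.plc, float)
        if np.any(self.pressures > 0):
            raise ValidationError("xylem pressures must be <= 0 MPa")
        if np.any((self.plc < 0) | (self.plc > 100)):
            raise ValidationError("PLC must lie in [0, 100]")
        if len(self.pressures) != len(self.plc):
            raise ValidationError("pressures and plc differ in length")

    @classmethod
    def from_conductance(cls, tree_id, pressures, ks,
                         reference_pressure=REFERENCE_PRESSURE):
        pressures = np.asarray(pressures, float)
        ks = np.asarray(ks, float)
        ref = pressures >= reference_pressure - 1e-9
        if not ref.any():
            raise ValidationError(
                f"no reference point at or above {reference_pressure} MPa")
        kmax = float(ks[ref].mean())
        return cls(tree_id, pressures, plc(ks, kmax), kmax=kmax)


@dataclass
class VulnerabilityFit:
    """Fitted sigmoid parameters with analytic thresholds and diagnostics."""

    tree_id: str
    p50: float              # MPa
    slope: float            # % MPa^-1 at P50
    p12: float
    p88: float
    residual_sd: float
    covariance: np.ndarray | None
    success: bool = True
    message: str = "converged"
    ci_p50: tuple | None = None
    n_points: int = 0

    @property
    def safety_margin_reference(self):
        return self.p50


def fit_vulnerability_curve(curve: VulnerabilityCurve,
                            n_bootstrap: int = 0, seed: int = 0) -> VulnerabilityFit:
    """Nonlinear least-squares fit of the sigmoid vulnerability curve.

    Degenerate curves (PLC never leaves 0 or 100) raise
    :class:`DegenerateCurveError`; a fit that fails to converge is
    returned with ``success=False`` and the solver message, so batch
    pipelines can keep going. Optional parametric bootstrap (residual
    resampling from the fitted curve) gives a percentile 95 % CI on P50.
    """
    psi, y = curve.pressures, curve.plc
    if len(np.unique(psi)) < 4:
        raise ValidationError("need >= 4 distinct pressures to fit")
    if y.max() < 5.0 or y.min() > 95.0:
        raise DegenerateCurveError(
            f"curve {curve.tree_id}: PLC spans [{y.min():.1f}, {y.max():.1f}]; "
            "no information about the midpoint")

    # initial guess: pressure nearest 50 % PLC, moderate slope
    p50_0 = float(psi[np.argmin(np.abs(y - 50.0))])
    guess = (min(p50_0, -0.1), 40.0)
    try:
        popt, pcov = curve_fit(
            lambda p, p50, s: sigmoid_plc(p, p50, s), psi, y,
            p0=guess, bounds=([-20.0, 0.1], [-1e-6, 1000.0]), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - exercised via diagnostics path
        return VulnerabilityFit(curve.tree_id, float("nan"), float("nan"),
                                float("nan"), float("nan"), float("nan"),
                                None, success=False, message=str(exc),
                                n_points=len(psi))
    p50, slope = float(popt[0]), float(popt[1])
    resid = y - sigmoid_plc(psi, p50, slope)
    residual_sd = float(np.sqrt(np.mean(resid ** 2)))
    fit = VulnerabilityFit(
        curve.tree_id, p50, slope,
        p12=float(pressure_at_plc(12, p50, slope)),
        p88=float(pressure_at_plc(88, p50, slope)),
        residual_sd=residual_sd, covariance=pcov, n_points=len(psi))

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = sigmoid_plc(psi, p50, slope)
        draws = []
        for _ in range(n_bootstrap):
            yb = np.clip(fitted + rng.normal(0, max(residual_sd, 1e-12), len(psi)),
                         0, 100)
            try:
                pb, _ = curve_fit(lambda p, a, b: sigmoid_plc(p, a, b), psi, yb,
                                  p0=(p50, slope),
                                  bounds=([-20.0, 0.1], [-1e-6, 1000.0]),
                                  maxfev=5000)
                draws.append(pb[0])
            except RuntimeError:
                continue
        if draws:
            fit.ci_p50 = (float(np.percentile(draws, 2.5)),
                          float(np.percentile(draws, 97.5)))
    return fit


def native_embolism(n_embolized, n_total, denominator="total"):
    """Native embolism percentage from tracheid counts.

    ``denominator='total'`` (default) reports embolized tracheids as a
    share of all tracheids, directly comparable with PLC;
    ``'functional'`` reports the embolized-to-functional ratio.
    """
    if n_total <= 0:
        raise DomainError("n_total must be > 0")
    if not 0 <= n_embolized <= n_total:
        raise DomainError("need 0 <= n_embolized <= n_total")
    if denominator == "total":
        return 100.0 * n_embolized / n_total
    if denominator == "functional":
        n_func = n_total - n_embolized
        if n_func == 0:
            raise DomainError("no functional tracheids; ratio undefined")
        return 100.0 * n_embolized / n_func
    raise ValueError(f"unknown denominator {denominator!r}")


def assess_against_thresholds(fit: VulnerabilityFit, water_potentials: dict,
                              plc_threshold=PLC_MORTALITY_THRESHOLD):
    """Hydraulic safety margins (psi_md - P50) per date.

    ``water_potentials`` maps date labels to midday xylem pressures
    (MPa). Each entry reports the margin, the PLC the fitted curve
    predicts at that pressure, and whether it exceeds the conventional
    50 % mortality threshold.
    """
    report = []
    for date, psi in water_potentials.items():
        predicted = float(sigmoid_plc(psi, fit.p50, fit.slope))
        report.append({
            "date": date,
            "psi": float(psi),
            "safety_margin": float(psi - fit.p50),
            "predicted_plc": predicted,
            "exceeds_plc_threshold": predicted >= plc_threshold,
        })
    return report
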