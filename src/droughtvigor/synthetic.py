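"""Synthetic declining / non-declining (D / ND) cohort generator.

Every measurement stream the analysis consumes — tree metadata, ring
widths, tracheid and pit anatomy, vulnerability curves, needle
desiccation series, water potentials, water isotopes, wood d13C and
monthly climate — is simulated with the class contrasts the field
study design assumes: declining trees are smaller and slower-growing,
form tracheids with narrower lumina and thinner walls, have pits with
wider apertures (hence lower torus overlap and valve effect), are less
able to reach deep soil water in late summer, lose more water after
stomatal closure (higher gmin), and are slightly less
cavitation-resistant (less negative P50 but higher native PLC).

Group means and their standard errors default to the cohort values of
the motivating field study (n = 15 trees per class for tree-level
traits, n = 5 for wood anatomy); standard deviations are recovered as
SE * sqrt(n). Traits are drawn independently within class; a
correlation hook exists but ships as identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .carbon import d13c_wood_from_discrimination, load_atmospheric_reference
from .exceptions import ConfigurationError, DomainError
from .hydraulics import VulnerabilityCurve, sigmoid_plc
from .leaf import DesiccationSeries, gmin_to_mass_slope

# ---------------------------------------------------------------------------
# trait table: mean_D, mean_ND, se_D, se_ND, n behind the SE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    mean_d: float
    mean_nd: float
    se_d: float
    se_nd: float
    n: int

    def sd(self, cls: str) -> float:
        se = self.se_d if cls == "D" else self.se_nd
        return se * np.sqrt(self.n)

    def mean(self, cls: str) -> float:
        return self.mean_d if cls == "D" else self.mean_nd


def default_traits() -> dict:
    return {
        "dbh": TraitSpec(21.3, 26.1, 0.7, 0.9, 15),              # cm
        "height": TraitSpec(5.8, 6.3, 0.2, 0.1, 15),             # m
        "age": TraitSpec(88, 92, 2, 2, 15),                      # years at 1.3 m
        "soil_depth": TraitSpec(31.1, 45.8, 2.9, 4.8, 15),       # cm
        "predawn_psi": TraitSpec(-0.52, -0.47, 0.04, 0.02, 15),  # MPa
        "midday_psi": TraitSpec(-1.39, -1.21, 0.05, 0.06, 15),   # MPa
        "leaf_area": TraitSpec(91.20, 106.32, 17.47, 10.32, 15),  # cm^2 (20 needles)
        "leaf_dry_mass": TraitSpec(1.82, 2.28, 0.33, 0.23, 15),  # g (20 needles)
        "gmin": TraitSpec(0.84, 0.64, 0.08, 0.05, 15),           # mmol m^-2 s^-1
        "ring_width": TraitSpec(0.37, 0.45, 0.02, 0.02, 15),     # mm
        "lumen_diameter": TraitSpec(21.5, 24.3, 0.6, 0.7, 5),    # um
        "wall_thickness": TraitSpec(9.34, 9.78, 0.14, 0.11, 5),  # um (double wall)
        "torus_overlap": TraitSpec(0.43, 0.48, 0.01, 0.01, 5),
        "margo_flexibility": TraitSpec(0.41, 0.47, 0.01, 0.02, 5),
        "pit_membrane": TraitSpec(10.5, 12.0, 0.2, 0.2, 5),      # um, Dm
        "p50": TraitSpec(-3.18, -3.34, 0.04, 0.04, 15),          # MPa
        "plc": TraitSpec(45.0, 25.0, 3.0, 3.0, 15),              # % native
        "starch": TraitSpec(2.5, 2.5, 0.3, 0.3, 15),             # % dry matter
        "soluble_sugars": TraitSpec(4.5, 4.5, 0.4, 0.4, 15),     # % dry matter
    }


# direction of the expected class contrast on the trait value
# (for P50 and midday psi the comparison is on the signed MPa value)
EXPECTED_DIRECTIONS = {
    "dbh": "D<ND", "height": "D<ND", "soil_depth": "D<ND",
    "midday_psi": "D<ND", "ring_width": "D<ND", "bai": "D<ND",
    "lumen_diameter": "D<ND", "wall_thickness": "D<ND",
    "torus_overlap": "D<ND", "margo_flexibility": "D<ND",
    "valve_effect": "D<ND", "pit_aperture": "D>ND",
    "plc": "D>ND", "p50": "D>ND", "gmin": "D>ND",
    "xylem_d18O": "D>ND",  # shallower water = isotopically enriched
}

# crown defoliation (%) per monitoring year: mean_D, mean_ND, se_D, se_ND
DEFAULT_DEFOLIATION = {
    2020: (58, 11, 3, 2), 2021: (75, 18, 3, 2), 2022: (79, 19, 3, 3),
    2023: (80, 22, 5, 3), 2024: (84, 21, 3, 3),
}

SPRING_DATE, LATE_SUMMER_DATE = "2020-06-23", "2020-09-08"


def default_isotope_params() -> dict:
    """Source-water isotope structure for the two sampling dates.

    Groundwater sits on the meteoric line; soils are evaporatively
    enriched along a date-specific evaporation line (shallower = more
    enriched, late summer more than spring). ND xylem follows the
    current line near the deep-soil pool; D xylem is shallower in both
    seasons and, in late summer, stays on the *spring* line (uncoupled
    from current soil water).
    """
    return {
        "groundwater_d18O": -9.0,
        "evap_slope": {"spring": 5.2, "late_summer": 4.6},
        "source_d18O": {
            "spring": {"well": -9.2, "river": -8.8,
                       "soil-15-30": -6.5, "soil-0-15": -4.5},
            "late_summer": {"well": -9.2, "river": -8.8,
                            "soil-15-30": -5.0, "soil-0-15": -2.5},
        },
        "xylem_d18O": {
            "spring": {"xylem-D": -5.7, "xylem-ND": -6.3, "xylem-oak": -8.0},
            "late_summer": {"xylem-D": -3.9, "xylem-ND": -4.9, "xylem-oak": -7.5},
        },
        "d18O_sd": 0.25, "line_sd": 1.0, "xylem_line_sd": 1.2,
        "n_soil": 4, "n_well": 3, "n_river": 2, "n_oak": 5,
    }


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic D/ND cohort."""

    n_trees_per_class: int = 15
    year_range: tuple = (1935, 2020)
    seed: int = 42
    traits: dict = field(default_factory=default_traits)
    defoliation_by_year: dict = field(default_factory=lambda: dict(DEFAULT_DEFOLIATION))
    drought_years: list = field(default_factory=lambda: [1986, 1995, 2005, 2012, 2017])
    drought_factor: dict = field(default_factory=lambda: {"D": 0.5, "ND": 0.75})
    climate_trend: float = 0.25          # degC per decade warming
    climate_years: tuple = (1920, 2018)
    n_deaths: dict = field(default_factory=lambda: {"D": 8, "ND": 1})
    monitoring_years: tuple = (2020, 2024)
    # anatomy / carbon subsets (cored subsample, as in the field design)
    n_anatomy_trees: int = 5
    n_carbon_trees: int = 5
    anatomy_years: tuple = (2000, 2020)
    tracheids_per_ring: int = 20
    pits_per_tree_period: int = 10
    # within-tree dispersions (no published variance partition; see docs)
    within_tree_sd: dict = field(default_factory=lambda: {
        "lumen_diameter": 3.0, "wall_thickness": 0.8,
        "torus_overlap": 0.04, "margo_flexibility": 0.04,
        "pit_membrane": 0.8,
    })
    # growth model
    year_effect_sd: float = 0.15
    ring_noise_sd: float = 0.10
    age_trend_strength: float = 0.6
    # vulnerability curves
    vc_pressures: tuple = (-0.5, -1.0, -1.5, -2.0, -2.5, -3.0, -3.5, -4.0, -4.5, -5.0)
    vc_slope_mean: float = 40.0          # % MPa^-1
    vc_slope_sd: float = 4.0
    vc_noise_sd: float = 2.0             # % PLC
    # desiccation
    desiccation_duration: float = 21600.0  # s (6 h)
    desiccation_samples: int = 25
    desiccation_noise_sd: float = 0.0005   # g
    stomatal_fraction: float = 0.15
    # iWUE divergence window (ND transiently more efficient)
    iwue_divergence_years: tuple = (2014, 2017)
    iwue_divergence_delta: float = 1.2     # permil reduction of ND D13C
    baseline_delta13c: float = 17.0        # permil discrimination baseline
    delta13c_tree_sd: float = 0.25
    delta13c_year_sd: float = 0.2
    isotope_params: dict = field(default_factory=default_isotope_params)
    trait_correlation: np.ndarray | None = None  # hook; identity when None

    def validate(self) -> "CohortConfig":
        if self.n_trees_per_class < 2:
            raise ConfigurationError("n_trees_per_class must be >= 2")
        if self.year_range[1] < self.year_range[0]:
            raise ConfigurationError("year_range is empty")
        for name, spec in self.traits.items():
            if spec.se_d <= 0 or spec.se_nd <= 0:
                raise ConfigurationError(f"traits[{name}]: dispersions must be > 0")
        for name, direction in EXPECTED_DIRECTIONS.items():
            if name not in self.traits:
                continue
            spec = self.traits[name]
            if direction == "D<ND" and not spec.mean_d < spec.mean_nd:
                raise ConfigurationError(
                    f"traits[{name}]: expected D < ND, got {spec.mean_d} vs {spec.mean_nd}")
            if direction == "D>ND" and not spec.mean_d > spec.mean_nd:
                raise ConfigurationError(
                    f"traits[{name}]: expected D > ND, got {spec.mean_d} vs {spec.mean_nd}")
        if not 0 <= self.stomatal_fraction < 1:
            raise ConfigurationError("stomatal_fraction must lie in [0, 1)")
        if self.vc_noise_sd < 0 or self.desiccation_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        return self

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["traits"] = {k: dataclasses.asdict(v) for k, v in self.traits.items()}
        d["trait_correlation"] = (None if self.trait_correlation is None
                                  else np.asarray(self.trait_correlation).tolist())
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["traits"] = {k: TraitSpec(**v) for k, v in d["traits"].items()}
        d["defoliation_by_year"] = {int(k): tuple(v)
                                    for k, v in d["defoliation_by_year"].items()}
        for key in ("year_range", "climate_years", "monitoring_years",
                    "anatomy_years", "vc_pressures", "iwue_divergence_years"):
            d[key] = tuple(d[key])
        if d.get("trait_correlation") is not None:
            d["trait_correlation"] = np.asarray(d["trait_correlation"])
        return cls(**d)


@dataclass
class CohortDataset:
    """All simulated measurement streams of one cohort, keyed by tree id."""

    config: CohortConfig
    trees: pd.DataFrame
    ring_widths: pd.DataFrame
    tracheids: pd.DataFrame
    pits_stem: pd.DataFrame
    pits_branch: pd.DataFrame
    vulnerability: pd.DataFrame
    desiccation: pd.DataFrame
    water_potentials: pd.DataFrame
    isotopes: pd.DataFrame
    carbon: pd.DataFrame
    climate: pd.DataFrame

    _STREAMS = ["trees", "ring_widths", "tracheids", "pits_stem", "pits_branch",
                "vulnerability", "desiccation", "water_potentials", "isotopes",
                "carbon", "climate"]

    def validate(self):
        ids = set(self.trees["tree_id"])
        for stream in self._STREAMS[1:]:
            df = getattr(self, stream)
            if "tree_id" in df.columns:
                orphan = set(df["tree_id"]) - ids
                if orphan:
                    raise ConfigurationError(
                        f"stream {stream} references unknown trees: {sorted(orphan)[:3]}")
        return self

    def write(self, directory):
        """Write every stream as TSV plus the resolved config sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for stream in self._STREAMS:
            getattr(self, stream).to_csv(directory / f"{stream}.tsv",
                                         sep="\t", index=False)
        (directory / "config.json").write_text(self.config.to_json())

    @classmethod
    def read(cls, directory) -> "CohortDataset":
        directory = Path(directory)
        config = CohortConfig.from_json((directory / "config.json").read_text())
        frames = {s: pd.read_csv(directory / f"{s}.tsv", sep="\t")
                  for s in cls._STREAMS}
        return cls(config=config, **frames).validate()

    def vulnerability_curves(self) -> list:
        out = []
        for tid, g in self.vulnerability.groupby("tree_id", sort=False):
            out.append(VulnerabilityCurve(str(tid), g["pressure"].to_numpy(),
                                          g["plc"].to_numpy()))
        return out

    def desiccation_series(self) -> list:
        meta = self.trees.set_index("tree_id")
        out = []
        for tid, g in self.desiccation.groupby("tree_id", sort=False):
            out.append(DesiccationSeries(
                str(tid), g["time_s"].to_numpy(), g["mass_g"].to_numpy(),
                leaf_area=float(meta.loc[tid, "desiccation_area_m2"])))
        return out


# ---------------------------------------------------------------------------
# stream generators
# ---------------------------------------------------------------------------

def generate_vulnerability_curve(p50, slope, pressures, noise_sd=0.0,
                                 rng=None, tree_id="synthetic"):
    """PLC points from the true sigmoid plus Gaussian observation noise."""
    if p50 >= 0:
        raise DomainError("p50 must be negative (MPa)")
    pressures = np.asarray(pressures, float)
    if np.any(pressures > 0):
        raise DomainError("pressures must be <= 0 MPa")
    values = sigmoid_plc(pressures, p50, slope)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        values = values + rng.normal(0.0, noise_sd, len(pressures))
    return VulnerabilityCurve(tree_id, pressures, np.clip(values, 0.0, 100.0))


def generate_desiccation_series(gmin_true, area, temperature=25.0,
                                duration=21600.0, n_samples=25, noise_sd=0.0,
                                stomatal_fraction=0.0, stomatal_factor=3.0,
                                mass0=1.0, rng=None, tree_id="synthetic"):
    """Needle mass-loss series whose cuticular slope encodes ``gmin_true``.

    An optional initial stomatal phase (first ``stomatal_fraction`` of
    the record) loses mass ``stomatal_factor`` times faster before the
    linear cuticular phase takes over.
    """
    if area <= 0:
        raise DomainError("area must be > 0")
    if gmin_true < 0:
        raise DomainError("gmin_true must be >= 0")
    if n_samples < 5:
        raise DomainError("need >= 5 samples")
    times = np.linspace(0.0, duration, n_samples)
    slope = gmin_to_mass_slope(gmin_true, area, temperature)
    t_break = stomatal_fraction * duration
    masses = np.where(
        times <= t_break,
        mass0 + stomatal_factor * slope * times,
        mass0 + stomatal_factor * slope * t_break + slope * (times - t_break))
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        masses = masses + rng.normal(0.0, noise_sd, n_samples)
    masses = np.maximum(masses, 1e-6)
    return DesiccationSeries(tree_id, times, masses, leaf_area=area,
                             chamber_temperature=temperature)


def _draw_trait(rng, cfg, name, cls, n, lower=None, upper=None):
    spec = cfg.traits[name]
    vals = rng.normal(spec.mean(cls), spec.sd(cls), n)
    if lower is not None or upper is not None:
        vals = np.clip(vals, lower, upper)
    return vals


def _generate_trees(rng, cfg):
    rows = []
    for cls in ("D", "ND"):
        n = cfg.n_trees_per_class
        cols = {
            "dbh": _draw_trait(rng, cfg, "dbh", cls, n, lower=5.0),
            "height": _draw_trait(rng, cfg, "height", cls, n, lower=1.0),
            "age": np.rint(_draw_trait(rng, cfg, "age", cls, n, lower=20)),
            "soil_depth": _draw_trait(rng, cfg, "soil_depth", cls, n, lower=5.0),
            "gmin": _draw_trait(rng, cfg, "gmin", cls, n, lower=0.05),
            "leaf_area": _draw_trait(rng, cfg, "leaf_area", cls, n, lower=20.0),
            "leaf_dry_mass": _draw_trait(rng, cfg, "leaf_dry_mass", cls, n, lower=0.3),
            "p50_true": np.clip(_draw_trait(rng, cfg, "p50", cls, n), None, -0.5),
            "plc_native": np.clip(_draw_trait(rng, cfg, "plc", cls, n), 0, 100),
            "starch": _draw_trait(rng, cfg, "starch", cls, n, lower=0.0),
            "soluble_sugars": _draw_trait(rng, cfg, "soluble_sugars", cls, n, lower=0.0),
            "ring_width_mean": _draw_trait(rng, cfg, "ring_width", cls, n, lower=0.05),
        }
        defol = {}
        for year, (md, mnd, sed, send) in sorted(cfg.defoliation_by_year.items()):
            mean, se = (md, sed) if cls == "D" else (mnd, send)
            raw = rng.normal(mean, se * np.sqrt(cfg.n_trees_per_class), n)
            defol[f"defoliation_{year}"] = np.clip(np.rint(raw / 5) * 5, 0, 100)
        # deaths within the monitoring window, never resurrecting
        first, last = cfg.monitoring_years
        n_dead = min(cfg.n_deaths.get(cls, 0), n)
        death_year = np.full(n, np.nan)
        if n_dead:
            dead_idx = rng.choice(n, size=n_dead, replace=False)
            death_year[dead_idx] = rng.integers(first + 1, last + 1, n_dead)
        alive = {f"alive_{y}": (~(death_year <= y)).astype(bool)
                 for y in range(first, last + 1)}
        for i in range(n):
            row = {"tree_id": f"{cls}{i + 1:02d}", "vigour_class": cls}
            row.update({k: v[i] for k, v in cols.items()})
            row.update({k: v[i] for k, v in defol.items()})
            row.update({k: bool(v[i]) for k, v in alive.items()})
            row["death_year"] = death_year[i]
            rows.append(row)
    trees = pd.DataFrame(rows)
    trees["nsc_total"] = trees["starch"] + trees["soluble_sugars"]
    # desiccation uses 10 of the 20 collected needles; projected area basis
    trees["desiccation_area_m2"] = trees["leaf_area"] / 2.0 * 1e-4
    return trees


def _generate_ring_widths(rng, cfg, trees):
    y0, y1 = cfg.year_range
    years = np.arange(y0, y1 + 1)
    n_years = len(years)
    # common high-frequency year effect shared by every tree (cross-datable)
    year_effect = np.exp(rng.normal(0.0, cfg.year_effect_sd, n_years))
    year_effect /= year_effect.mean()
    # juvenile-to-mature age trend, normalised to mean 1
    rel_age = np.linspace(0.0, 1.0, n_years)
    age_trend = 1.0 + cfg.age_trend_strength * (0.5 - rel_age)
    age_trend /= age_trend.mean()
    drought_mask = np.isin(years, cfg.drought_years)
    rows = []
    for t in trees.itertuples():
        factor = np.where(drought_mask, cfg.drought_factor[t.vigour_class], 1.0)
        noise = np.exp(rng.normal(0.0, cfg.ring_noise_sd, n_years))
        widths = t.ring_width_mean * age_trend * year_effect * factor * noise
        rows.append(pd.DataFrame({"tree_id": t.tree_id, "year": years,
                                  "width": widths}))
    return pd.concat(rows, ignore_index=True)


def _generate_tracheids(rng, cfg, trees):
    y0, y1 = cfg.anatomy_years
    rows = []
    for cls in ("D", "ND"):
        sub = trees[trees["vigour_class"] == cls].head(cfg.n_anatomy_trees)
        for t in sub.itertuples():
            lumen_tree = rng.normal(cfg.traits["lumen_diameter"].mean(cls),
                                    cfg.traits["lumen_diameter"].sd(cls))
            wall_tree = rng.normal(cfg.traits["wall_thickness"].mean(cls),
                                   cfg.traits["wall_thickness"].sd(cls))
            for year in range(y0, y1 + 1):
                k = cfg.tracheids_per_ring
                lumen = np.maximum(rng.normal(
                    lumen_tree, cfg.within_tree_sd["lumen_diameter"], k), 2.0)
                wall = np.maximum(rng.normal(
                    wall_tree, cfg.within_tree_sd["wall_thickness"], k), 0.5)
                rows.append(pd.DataFrame({
                    "tree_id": t.tree_id, "year": year,
                    "row_index": (np.arange(k) % 5) + 1,
                    "lumen_diameter": lumen, "double_wall_thickness": wall}))
    return pd.concat(rows, ignore_index=True)


def _pits_for(rng, cfg, cls, tree_id, year, n_pits,
              overlap_mean, flex_mean):
    """Draw pits via (overlap, flexibility, Dm) and derive the diameters."""
    w = cfg.within_tree_sd
    overlap = np.clip(rng.normal(overlap_mean, w["torus_overlap"], n_pits),
                      0.02, 0.9)
    flex = np.clip(rng.normal(flex_mean, w["margo_flexibility"], n_pits),
                   0.02, 0.9)
    dm = np.maximum(rng.normal(cfg.traits["pit_membrane"].mean(cls),
                               w["pit_membrane"], n_pits), 3.0)
    dt = dm * (1.0 - flex)
    da = dt * (1.0 - overlap)
    return pd.DataFrame({"tree_id": tree_id, "year": year,
                         "Da": da, "Dt": dt, "Dm": dm})


def _generate_pits(rng, cfg, trees):
    from .anatomy import DEFAULT_PIT_PERIODS
    stem_rows, branch_rows = [], []
    for cls in ("D", "ND"):
        spec_o = cfg.traits["torus_overlap"]
        spec_f = cfg.traits["margo_flexibility"]
        sub = trees[trees["vigour_class"] == cls].head(cfg.n_anatomy_trees)
        for t in sub.itertuples():
            o_tree = rng.normal(0.0, spec_o.sd(cls))
            f_tree = rng.normal(0.0, spec_f.sd(cls))
            for lo, hi in DEFAULT_PIT_PERIODS:
                # class divergence only appears in the final period;
                # earlier stem pits share the pooled (mid-class) means
                if hi >= 2017:
                    o_mean, f_mean = spec_o.mean(cls), spec_f.mean(cls)
                else:
                    o_mean = (spec_o.mean_d + spec_o.mean_nd) / 2
                    f_mean = (spec_f.mean_d + spec_f.mean_nd) / 2
                year = int(rng.integers(lo, hi + 1))
                stem_rows.append(_pits_for(
                    rng, cfg, cls, t.tree_id, year, cfg.pits_per_tree_period,
                    o_mean + o_tree, f_mean + f_tree))
            branch_rows.append(_pits_for(
                rng, cfg, cls, t.tree_id, 2021, cfg.pits_per_tree_period,
                spec_o.mean(cls) + o_tree, spec_f.mean(cls) + f_tree))
    return (pd.concat(stem_rows, ignore_index=True),
            pd.concat(branch_rows, ignore_index=True))


def _generate_vulnerability(rng, cfg, trees):
    rows = []
    for t in trees.itertuples():
        slope = max(rng.normal(cfg.vc_slope_mean, cfg.vc_slope_sd), 10.0)
        curve = generate_vulnerability_curve(
            t.p50_true, slope, cfg.vc_pressures, noise_sd=cfg.vc_noise_sd,
            rng=rng, tree_id=t.tree_id)
        rows.append(pd.DataFrame({
            "tree_id": t.tree_id, "pressure": curve.pressures,
            "plc": curve.plc, "true_p50": t.p50_true, "true_slope": slope}))
    return pd.concat(rows, ignore_index=True)


def _generate_desiccation(rng, cfg, trees):
    rows = []
    for t in trees.itertuples():
        series = generate_desiccation_series(
            t.gmin, t.desiccation_area_m2,
            duration=cfg.desiccation_duration,
            n_samples=cfg.desiccation_samples,
            noise_sd=cfg.desiccation_noise_sd,
            stomatal_fraction=cfg.stomatal_fraction,
            rng=rng, tree_id=t.tree_id)
        rows.append(pd.DataFrame({"tree_id": t.tree_id,
                                  "time_s": series.times,
                                  "mass_g": series.masses}))
    return pd.concat(rows, ignore_index=True)


# progressive summer drawdown added to the early-June baseline means
_PSI_DATES = {"2020-06-22": (0.0, 0.0), "2020-07-28": (-0.20, -0.55),
              "2020-09-08": (-0.35, -0.85)}


def _generate_water_potentials(rng, cfg, trees):
    rows = []
    for t in trees.itertuples():
        cls = t.vigour_class
        pd_spec = cfg.traits["predawn_psi"]
        md_spec = cfg.traits["midday_psi"]
        for date, (d_pd, d_md) in _PSI_DATES.items():
            pd_psi = rng.normal(pd_spec.mean(cls) + d_pd,
                                pd_spec.sd(cls))
            md_psi = rng.normal(md_spec.mean(cls) + d_md,
                                md_spec.sd(cls))
            md_psi = min(md_psi, pd_psi)  # midday never wetter than predawn
            rows.append({"tree_id": t.tree_id, "vigour_class": cls,
                         "date": date, "time_of_day": "predawn",
                         "psi": min(pd_psi, -0.01)})
            rows.append({"tree_id": t.tree_id, "vigour_class": cls,
                         "date": date, "time_of_day": "midday",
                         "psi": min(md_psi, -0.01)})
    return pd.DataFrame(rows)


def _generate_isotopes(rng, cfg, trees):
    p = cfg.isotope_params
    gw18 = p["groundwater_d18O"]
    gw2h = 8.06 + 7.77 * gw18  # groundwater sits on the meteoric line

    def evap_line_d2h(d18o, season):
        return gw2h + p["evap_slope"][season] * (d18o - gw18)

    rows = []
    counter = [0]

    def add(date, season, source_class, mean18, on_spring_line=False,
            sd18=None, sd_line=None):
        sd18 = p["d18O_sd"] if sd18 is None else sd18
        sd_line = p["line_sd"] if sd_line is None else sd_line
        d18o = rng.normal(mean18, sd18)
        line_season = "spring" if on_spring_line else season
        d2h = evap_line_d2h(d18o, line_season) + rng.normal(0.0, sd_line)
        counter[0] += 1
        rows.append({"sample_id": f"S{counter[0]:03d}", "date": date,
                     "source_class": source_class, "d18O": d18o, "d2H": d2h})

    for season, date in (("spring", SPRING_DATE),
                         ("late_summer", LATE_SUMMER_DATE)):
        for src, mean18 in p["source_d18O"][season].items():
            n = {"well": p["n_well"], "river": p["n_river"]}.get(src, p["n_soil"])
            for _ in range(n):
                add(date, season, src, mean18)
        xy = p["xylem_d18O"][season]
        for t in trees.itertuples():
            cls = f"xylem-{t.vigour_class}"
            # declining trees in late summer keep the spring-line signature
            stale = cls == "xylem-D" and season == "late_summer"
            add(date, season, cls, xy[cls], on_spring_line=stale,
                sd_line=p["xylem_line_sd"])
        for _ in range(p["n_oak"]):
            add(date, season, "xylem-oak", xy["xylem-oak"],
                sd_line=p["xylem_line_sd"])
    return pd.DataFrame(rows)


def _generate_carbon(rng, cfg, trees, atmosphere):
    lo, hi = cfg.anatomy_years
    atm = atmosphere.set_index("year")
    div_lo, div_hi = cfg.iwue_divergence_years
    rows = []
    for cls in ("D", "ND"):
        sub = trees[trees["vigour_class"] == cls].head(cfg.n_carbon_trees)
        for t in sub.itertuples():
            tree_eff = rng.normal(0.0, cfg.delta13c_tree_sd)
            for year in range(lo, hi + 1):
                delta = cfg.baseline_delta13c + tree_eff \
                    + rng.normal(0.0, cfg.delta13c_year_sd)
                if cls == "ND" and div_lo <= year <= div_hi:
                    delta -= cfg.iwue_divergence_delta
                d13c_w = d13c_wood_from_discrimination(
                    delta, float(atm.loc[year, "d13C_atm"]))
                rows.append({"tree_id": t.tree_id, "year": year,
                             "d13C_wood": d13c_w})
    return pd.DataFrame(rows)


# Iberian interior monthly normals (Daroca-like: MAT ~12 degC, ~423 mm)
_TMAX_NORMAL = [8.8, 10.8, 14.6, 16.4, 20.9, 26.4, 30.4, 29.9, 25.2, 18.8, 12.8, 9.2]
_TMIN_NORMAL = [-0.7, -0.3, 1.8, 3.6, 7.3, 11.2, 13.9, 13.9, 10.9, 6.6, 2.4, 0.0]
_PRECIP_NORMAL = [25, 22, 30, 45, 55, 45, 25, 25, 35, 45, 38, 33]


def _generate_climate(rng, cfg):
    y0, y1 = cfg.climate_years
    rows = []
    for year in range(y0, y1 + 1):
        warming = cfg.climate_trend * (year - y0) / 10.0
        drought = year in cfg.drought_years
        for month in range(1, 13):
            tmax = _TMAX_NORMAL[month - 1] + warming + rng.normal(0.0, 1.5)
            tmin = _TMIN_NORMAL[month - 1] + warming + rng.normal(0.0, 1.2)
            tmin = min(tmin, tmax - 0.5)
            mu = _PRECIP_NORMAL[month - 1]
            precip = rng.gamma(2.0, mu / 2.0)
            if drought:
                tmax += 1.5
                tmin += 1.5
                precip *= 0.4
            rows.append({"year": year, "month": month, "tmax": tmax,
                         "tmin": tmin, "precip": precip})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a full synthetic cohort from a validated configuration.

    The same config (including seed) always yields a bit-identical
    dataset: every stream draws from one generator in a fixed order.
    """
    cfg = (config or CohortConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    atmosphere = load_atmospheric_reference()
    trees = _generate_trees(rng, cfg)
    dataset = CohortDataset(
        config=cfg,
        trees=trees,
        ring_widths=_generate_ring_widths(rng, cfg, trees),
        tracheids=_generate_tracheids(rng, cfg, trees),
        pits_stem=None, pits_branch=None,
        vulnerability=_generate_vulnerability(rng, cfg, trees),
        desiccation=_generate_desiccation(rng, cfg, trees),
        water_potentials=_generate_water_potentials(rng, cfg, trees),
        isotopes=_generate_isotopes(rng, cfg, trees),
        carbon=_generate_carbon(rng, cfg, trees, atmosphere),
        climate=_generate_climate(rng, cfg),
    )
    dataset.pits_stem, dataset.pits_branch = _generate_pits(rng, cfg, trees)
    return dataset.validate()
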