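"""Vigour classification, mortality rates and the cohort report.

The report binds every analysis module: it recomputes growth (BAI),
anatomy, hydraulic, leaf, isotope, carbon and climate contrasts between
the declining (D) and non-declining (ND) classes from a
:class:`~droughtvigor.synthetic.CohortDataset`, and closes with a
checklist comparing each observed contrast sign against the expected
direction.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import anatomy, carbon, climate, hydraulics, isotopes, leaf
from .exceptions import DomainError, ValidationError
from .growth import RingSeries, build_master_chronology, compare_bai_by_year, compute_bai, under_bark_radius
from .stats import compare_groups
from .synthetic import EXPECTED_DIRECTIONS, LATE_SUMMER_DATE, SPRING_DATE

DEFOLIATION_D_THRESHOLD = 60.0   # % crown defoliation above which a tree is declining
DEFOLIATION_ND_THRESHOLD = 40.0  # % below which a tree is non-declining


def classify_vigour(defoliation):
    """Vigour class from crown defoliation (%): D above 60, ND below 40.

    Trees in the intermediate [40, 60] band are 'unclassified' and
    excluded from class analyses by design.
    """
    if not 0 <= defoliation <= 100:
        raise ValidationError(f"defoliation {defoliation} outside [0, 100]")
    if defoliation > DEFOLIATION_D_THRESHOLD:
        return "D"
    if defoliation < DEFOLIATION_ND_THRESHOLD:
        return "ND"
    return "unclassified"


def annual_mortality_rate(n_initial, n_dead, n_years):
    """Simple annualised mortality: 100 * n_dead / (n_initial * n_years), % yr^-1."""
    if n_initial <= 0:
        raise DomainError("n_initial must be > 0")
    if not 0 <= n_dead <= n_initial:
        raise DomainError("need 0 <= n_dead <= n_initial")
    if n_years < 1:
        raise DomainError("n_years must be >= 1")
    return 100.0 * n_dead / (n_initial * n_years)


def annual_mortality_rate_compound(n_initial, n_dead, n_years):
    """Compound-interest alternative: 100 * (1 - (1 - m)^(1/T))."""
    if n_initial <= 0:
        raise DomainError("n_initial must be > 0")
    surviving = (n_initial - n_dead) / n_initial
    return 100.0 * (1.0 - surviving ** (1.0 / n_years))


def _split(trees: pd.DataFrame):
    return {cls: trees[trees["vigour_class"] == cls] for cls in ("D", "ND")}


def _class_values(df, id_col, value_col, trees):
    cls_of = trees.set_index("tree_id")["vigour_class"]
    merged = df.copy()
    merged["vigour_class"] = merged[id_col].map(cls_of)
    return {cls: g[value_col].to_numpy()
            for cls, g in merged.groupby("vigour_class") if cls in ("D", "ND")}


def _comparison_dict(comp):
    return {"trait": comp.trait, "groups": comp.groups,
            "test_used": comp.test_used, "statistic": comp.statistic,
            "p": comp.p, "letters": comp.letters, "transform": comp.transform,
            "significant": comp.significant}


def run_report(dataset, bark_fraction=0.15) -> dict:
    """Full D vs ND cohort report; deterministic for a given dataset."""
    trees = dataset.trees
    by_class = _split(trees)
    cfg = dataset.config
    report = {"n_trees": {cls: int(len(g)) for cls, g in by_class.items()},
              "sections": {}}

    # --- cohort metadata ---------------------------------------------------
    first, last = cfg.monitoring_years
    n_years = last - first + 1
    mortality = {}
    for cls, g in by_class.items():
        n_dead = int(g["death_year"].notna().sum())
        mortality[cls] = {
            "n_initial": int(len(g)), "n_dead": n_dead, "n_years": n_years,
            "rate_pct_per_year": annual_mortality_rate(len(g), n_dead, n_years)}
    traits = {}
    for trait in ("dbh", "height", "age", "soil_depth",
                  "starch", "soluble_sugars", "nsc_total",
                  f"defoliation_{last}"):
        comp = compare_groups({c: g[trait].to_numpy() for c, g in by_class.items()},
                              trait=trait)
        traits[trait] = _comparison_dict(comp)
    report["sections"]["cohort"] = {"mortality": mortality, "traits": traits}

    # --- growth ------------------------------------------------------------
    series = {tid: RingSeries(str(tid), int(g["year"].min()),
                              g.sort_values("year")["width"].to_numpy())
              for tid, g in dataset.ring_widths.groupby("tree_id")}
    master, depth = build_master_chronology(list(series.values()))
    radii = {t.tree_id: under_bark_radius(t.dbh, bark_fraction)
             for t in trees.itertuples()}
    bai = {tid: compute_bai(s, radii[tid]) for tid, s in series.items()}
    cls_of = trees.set_index("tree_id")["vigour_class"]
    bai_groups = {"D": [], "ND": []}
    for tid, b in bai.items():
        bai_groups[cls_of[tid]].append(b)
    bai_cmp = compare_bai_by_year(bai_groups["D"], bai_groups["ND"])
    mean_bai = {cls: float(np.mean([b.bai.mean() for b in group]))
                for cls, group in bai_groups.items()}
    report["sections"]["growth"] = {
        "master_chronology_span": [int(master.first_year), int(master.last_year)],
        "mean_bai_mm2": mean_bai,
        "wilcoxon_by_year": bai_cmp["table"].to_dict("records"),
        "significant_windows": bai_cmp["significant_windows"],
    }

    # --- wood & pit anatomy ------------------------------------------------
    ring_summary = anatomy.ring_anatomy_summary(dataset.tracheids)
    tree_anatomy = ring_summary.groupby("tree_id")[
        ["lumen_diameter", "double_wall_thickness", "thickness_to_span"]
    ].mean().reset_index()
    anat_cmp = {}
    for col in ("lumen_diameter", "double_wall_thickness", "thickness_to_span"):
        vals = _class_values(tree_anatomy, "tree_id", col, trees)
        anat_cmp[col] = _comparison_dict(compare_groups(vals, trait=col))
    branch_means = anatomy.pit_tree_means(dataset.pits_branch)
    pit_cmp = {}
    for col in anatomy.PIT_METRIC_NAMES + ["Da", "Dt", "Dm"]:
        vals = _class_values(branch_means, "tree_id", col, trees)
        pit_cmp[col] = _comparison_dict(compare_groups(vals, trait=col))
    d_pits = dataset.pits_stem[dataset.pits_stem["tree_id"].map(cls_of) == "D"]
    nd_pits = dataset.pits_stem[dataset.pits_stem["tree_id"].map(cls_of) == "ND"]
    periods = anatomy.compare_pit_periods(d_pits, nd_pits)
    report["sections"]["anatomy"] = {
        "tracheids": anat_cmp, "branch_pits": pit_cmp,
        "stem_pit_periods": periods.to_dict("records"),
    }

    # --- hydraulics ----------------------------------------------------------
    fits = {}
    for curve in dataset.vulnerability_curves():
        fit = hydraulics.fit_vulnerability_curve(curve)
        if fit.success:
            fits[curve.tree_id] = fit
    p50_table = pd.DataFrame({"tree_id": list(fits),
                              "p50": [f.p50 for f in fits.values()],
                              "slope": [f.slope for f in fits.values()]})
    p50_cmp = _comparison_dict(compare_groups(
        _class_values(p50_table, "tree_id", "p50", trees), trait="p50"))
    plc_cmp = _comparison_dict(compare_groups(
        {c: g["plc_native"].to_numpy() for c, g in by_class.items()},
        trait="plc_native"))
    # class-mean safety margin at the late-summer midday potential
    wp = dataset.water_potentials
    late_md = wp[(wp["date"] == "2020-09-08") & (wp["time_of_day"] == "midday")]
    margins = {}
    for cls in ("D", "ND"):
        psi = float(late_md[late_md["vigour_class"] == cls]["psi"].mean())
        p50_mean = float(p50_table[p50_table["tree_id"].map(cls_of) == cls]["p50"].mean())
        margins[cls] = {"psi_midday": psi, "p50_mean": p50_mean,
                        "safety_margin": psi - p50_mean}
    report["sections"]["hydraulics"] = {
        "p50": p50_cmp, "native_plc": plc_cmp, "safety_margins": margins,
        "n_fitted": len(fits),
    }

    # --- leaf ----------------------------------------------------------------
    lma_table = trees[["tree_id", "leaf_dry_mass", "leaf_area"]].copy()
    lma_table["lma"] = leaf.lma(lma_table["leaf_dry_mass"].to_numpy(),
                                lma_table["leaf_area"].to_numpy())
    lma_cmp = _comparison_dict(compare_groups(
        _class_values(lma_table, "tree_id", "lma", trees), trait="lma"))
    gmin_fits = {s.tree_id: leaf.fit_gmin(s) for s in dataset.desiccation_series()}
    gmin_table = pd.DataFrame({
        "tree_id": [tid for tid, f in gmin_fits.items() if f.success],
        "gmin": [f.gmin for f in gmin_fits.values() if f.success]})
    gmin_cmp = _comparison_dict(compare_groups(
        _class_values(gmin_table, "tree_id", "gmin", trees), trait="gmin"))
    wp_summary = leaf.summarize_water_potentials(dataset.water_potentials)
    june_md = wp[(wp["date"] == "2020-06-22") & (wp["time_of_day"] == "midday")]
    midday_cmp = _comparison_dict(compare_groups(
        {c: g["psi"].to_numpy() for c, g in june_md.groupby("vigour_class")},
        trait="midday_psi"))
    report["sections"]["leaf"] = {
        "lma": lma_cmp, "gmin": gmin_cmp, "midday_psi_june": midday_cmp,
        "water_potentials": wp_summary["summary"].to_dict("records"),
        "water_potential_tests": wp_summary["tests"].to_dict("records"),
        "flagged_tree_dates": wp_summary["flagged_tree_dates"],
    }

    # --- isotopes ------------------------------------------------------------
    iso = dataset.isotopes
    iso_section = {}
    for label, date in (("spring", SPRING_DATE), ("late_summer", LATE_SUMMER_DATE)):
        line = isotopes.evaporation_line(iso, date)
        day = iso[iso["date"] == date]
        offsets = {}
        for cls in ("xylem-D", "xylem-ND"):
            sel = day[day["source_class"] == cls]
            off = isotopes.line_offset(sel["d18O"].to_numpy(),
                                       sel["d2H"].to_numpy(), line)
            offsets[cls] = {"mean_abs_offset": float(np.mean(np.abs(off))),
                            "mean_offset": float(np.mean(off)), "n": len(sel)}
        iso_section[label] = {
            "evaporation_line": {"slope": line.slope, "intercept": line.intercept,
                                 "r_squared": line.r_squared, "n": line.n},
            "xylem_offsets": offsets,
            "depth_comparison": isotopes.compare_depth_signature(iso, date),
        }
    spring = iso[iso["date"] == SPRING_DATE]
    summer = iso[iso["date"] == LATE_SUMMER_DATE]
    iso_section["seasonal_shift"] = isotopes.seasonal_shift(
        spring, summer).to_dict("records")
    report["sections"]["isotopes"] = iso_section

    # --- carbon / iWUE -------------------------------------------------------
    carbon_cls = dataset.carbon.copy()
    carbon_cls["vigour_class"] = carbon_cls["tree_id"].map(cls_of)
    iwue_cmp = carbon.iwue_series_comparison(
        carbon_cls[carbon_cls["vigour_class"] == "D"][["tree_id", "year", "d13C_wood"]],
        carbon_cls[carbon_cls["vigour_class"] == "ND"][["tree_id", "year", "d13C_wood"]])
    report["sections"]["carbon"] = {
        "iwue_by_year": iwue_cmp["table"].to_dict("records"),
        "significant_windows": iwue_cmp["significant_windows"],
    }

    # --- climate -------------------------------------------------------------
    balance = climate.annual_water_balance(dataset.climate,
                                           latitude_deg=41.27, elevation_m=961)
    seasonal = climate.seasonal_aggregate(dataset.climate)
    trends = climate.seasonal_trends(seasonal, "tmean")
    report["sections"]["climate"] = {
        "driest_year": climate.driest_year(balance),
        "mean_balance_mm": float(balance["balance"].mean()),
        "seasonal_trends": trends.to_dict("records"),
    }

    # --- expectation checklist ----------------------------------------------
    observed = {
        "dbh": {c: float(g["dbh"].mean()) for c, g in by_class.items()},
        "height": {c: float(g["height"].mean()) for c, g in by_class.items()},
        "soil_depth": {c: float(g["soil_depth"].mean()) for c, g in by_class.items()},
        "bai": mean_bai,
        "midday_psi": {c: midday_cmp["groups"][c]["mean"] for c in ("D", "ND")},
        "lumen_diameter": {c: anat_cmp["lumen_diameter"]["groups"][c]["mean"]
                           for c in ("D", "ND")},
        "wall_thickness": {c: anat_cmp["double_wall_thickness"]["groups"][c]["mean"]
                           for c in ("D", "ND")},
        "torus_overlap": {c: pit_cmp["torus_overlap"]["groups"][c]["mean"]
                          for c in ("D", "ND")},
        "margo_flexibility": {c: pit_cmp["margo_flexibility"]["groups"][c]["mean"]
                              for c in ("D", "ND")},
        "valve_effect": {c: pit_cmp["valve_effect"]["groups"][c]["mean"]
                         for c in ("D", "ND")},
        "pit_aperture": {c: pit_cmp["Da"]["groups"][c]["mean"] for c in ("D", "ND")},
        "plc": {c: plc_cmp["groups"][c]["mean"] for c in ("D", "ND")},
        "p50": {c: p50_cmp["groups"][c]["mean"] for c in ("D", "ND")},
        "gmin": {c: gmin_cmp["groups"][c]["mean"] for c in ("D", "ND")},
        "xylem_d18O": {
            c: iso_section["late_summer"]["depth_comparison"]["isotopes"]["d18O"]
            ["summary"][f"xylem-{c}"]["mean"] for c in ("D", "ND")},
    }
    checklist = {}
    for trait, expected in EXPECTED_DIRECTIONS.items():
        if trait == "ring_width":
            continue  # subsumed by BAI
        vals = observed[trait]
        observed_dir = "D<ND" if vals["D"] < vals["ND"] else "D>ND"
        checklist[trait] = {"expected": expected, "observed": observed_dir,
                            "mean_D": vals["D"], "mean_ND": vals["ND"],
                            "match": observed_dir == expected}
    report["sections"]["expectations"] = checklist
    report["all_expected_contrasts_match"] = all(
        v["match"] for v in checklist.values())
    return report


def report_to_json(report: dict) -> str:
    """Deterministic machine-readable rendering."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")
    return json.dumps(report, indent=1, sort_keys=True, default=default,
                      allow_nan=True)


def render_report_text(report: dict) -> str:
    """Short human-readable summary of the cohort report."""
    lines = ["Cohort report (D = declining, ND = non-declining)", ""]
    mort = report["sections"]["cohort"]["mortality"]
    for cls in ("D", "ND"):
        m = mort[cls]
        lines.append(f"  {cls}: {m['n_dead']}/{m['n_initial']} trees died over "
                     f"{m['n_years']} yr -> {m['rate_pct_per_year']:.2f} % yr-1")
    lines.append("")
    lines.append("  Expectation checklist:")
    for trait, row in sorted(report["sections"]["expectations"].items()):
        mark = "OK " if row["match"] else "MISS"
        lines.append(f"    [{mark}] {trait:18s} expected {row['expected']}, "
                     f"D={row['mean_D']:.3f} ND={row['mean_ND']:.3f}")
    lines.append("")
    lines.append(f"  All expected contrasts match: "
                 f"{report['all_expected_contrasts_match']}")
    return "\n".join(lines)
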