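"""Synthetic cohort generator: determinism, configured contrasts,
parameter recovery and dataset round-trips."""

import warnings

import numpy as np
import pandas as pd
import pytest

from droughtvigor.climate import mann_kendall, seasonal_aggregate, seasonal_trends
from droughtvigor.exceptions import ConfigurationError, DomainError
from droughtvigor.hydraulics import fit_vulnerability_curve
from droughtvigor.isotopes import fit_isotope_line
from droughtvigor.leaf import fit_gmin
from droughtvigor.synthetic import (CohortConfig, CohortDataset, TraitSpec,
                                    generate_cohort,
                                    generate_desiccation_series,
                                    generate_vulnerability_curve)


class TestConfigValidation:
    def test_defaults_valid(self):
        CohortConfig().validate()

    def test_too_few_trees_named(self):
        with pytest.raises(ConfigurationError, match="n_trees_per_class"):
            CohortConfig(n_trees_per_class=1).validate()

    def test_empty_year_range_named(self):
        with pytest.raises(ConfigurationError, match="year_range"):
            CohortConfig(year_range=(2020, 2000)).validate()

    def test_nonpositive_dispersion_named(self):
        cfg = CohortConfig()
        cfg.traits["dbh"] = TraitSpec(21.3, 26.1, 0.0, 0.9, 15)
        with pytest.raises(ConfigurationError, match="dbh"):
            cfg.validate()

    def test_contrast_sign_violation_rejected(self):
        cfg = CohortConfig()
        cfg.traits["gmin"] = TraitSpec(0.5, 0.64, 0.08, 0.05, 15)  # D < ND: wrong
        with pytest.raises(ConfigurationError, match="gmin"):
            cfg.validate()

    def test_se_to_sd_conversion(self):
        spec = TraitSpec(21.3, 26.1, 0.7, 0.9, 15)
        assert spec.sd("D") == pytest.approx(0.7 * np.sqrt(15))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortConfig(seed=7, n_trees_per_class=4))
        b = generate_cohort(CohortConfig(seed=7, n_trees_per_class=4))
        for stream in CohortDataset._STREAMS:
            pd.testing.assert_frame_equal(getattr(a, stream), getattr(b, stream))

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=7, n_trees_per_class=4))
        b = generate_cohort(CohortConfig(seed=8, n_trees_per_class=4))
        assert not a.trees["dbh"].equals(b.trees["dbh"])

    def test_write_read_round_trip(self, tmp_path):
        a = generate_cohort(CohortConfig(seed=7, n_trees_per_class=3))
        a.write(tmp_path / "cohort")
        b = CohortDataset.read(tmp_path / "cohort")
        assert b.config.seed == 7
        pd.testing.assert_frame_equal(
            a.trees, b.trees, check_dtype=False, check_exact=False, rtol=1e-12)


class TestClassStructure:
    def test_large_cohort_mean_near_generating_mean(self):
        cfg = CohortConfig(n_trees_per_class=200, seed=5)
        ds = generate_cohort(cfg)
        d = ds.trees.query("vigour_class == 'D'")["dbh"]
        se = cfg.traits["dbh"].sd("D") / np.sqrt(200)
        assert abs(d.mean() - 21.3) < 3 * se

    def test_contrast_signs_by_construction(self, default_cohort):
        trees = default_cohort.trees
        means = trees.groupby("vigour_class")[
            ["dbh", "height", "soil_depth", "gmin", "p50_true", "plc_native"]
        ].mean()
        assert means.loc["D", "dbh"] < means.loc["ND", "dbh"]
        assert means.loc["D", "height"] < means.loc["ND", "height"]
        assert means.loc["D", "soil_depth"] < means.loc["ND", "soil_depth"]
        assert means.loc["D", "gmin"] > means.loc["ND", "gmin"]
        assert means.loc["D", "p50_true"] > means.loc["ND", "p50_true"]
        assert means.loc["D", "plc_native"] > means.loc["ND", "plc_native"]

    def test_nsc_sums_and_no_resurrection(self, default_cohort):
        trees = default_cohort.trees
        assert np.allclose(trees["nsc_total"],
                           trees["starch"] + trees["soluble_sugars"])
        alive = trees[[f"alive_{y}" for y in range(2020, 2025)]].to_numpy()
        assert (np.diff(alive.astype(int), axis=1) <= 0).all()

    def test_drought_years_suppress_d_more(self, default_cohort):
        rw = default_cohort.ring_widths.merge(
            default_cohort.trees[["tree_id", "vigour_class"]], on="tree_id")
        cfg = default_cohort.config
        rel = {}
        for cls, g in rw.groupby("vigour_class"):
            drought = g[g["year"].isin(cfg.drought_years)]["width"].mean()
            normal = g[~g["year"].isin(cfg.drought_years)]["width"].mean()
            rel[cls] = drought / normal
        assert rel["D"] < rel["ND"] < 1.0


class TestVulnerabilityGeneration:
    PRESSURES = np.arange(-0.5, -5.5, -0.5)

    def test_nonnegative_p50_rejected(self):
        with pytest.raises(DomainError):
            generate_vulnerability_curve(1.0, 40.0, self.PRESSURES)

    def test_midpoint_and_truncation(self):
        curve = generate_vulnerability_curve(-3.0, 40.0, [-0.01, -3.0, -10.0])
        assert curve.plc[1] == pytest.approx(50.0)
        assert curve.plc[0] == pytest.approx(0.0, abs=1.0)
        assert curve.plc[2] == pytest.approx(100.0, abs=1.0)
        assert (curve.plc >= 0).all() and (curve.plc <= 100).all()

    def test_generate_and_refit_recovers_p50(self):
        curve = generate_vulnerability_curve(-3.34, 37.0, self.PRESSURES)
        assert fit_vulnerability_curve(curve).p50 == pytest.approx(-3.34, abs=1e-6)


class TestDesiccationGeneration:
    def test_zero_gmin_constant_mass(self):
        s = generate_desiccation_series(0.0, 4e-3)
        assert np.ptp(s.masses) == 0.0

    def test_doubling_area_doubles_loss_rate(self):
        s1 = generate_desiccation_series(0.7, 4e-3)
        s2 = generate_desiccation_series(0.7, 8e-3)
        slope1 = np.polyfit(s1.times, s1.masses, 1)[0]
        slope2 = np.polyfit(s2.times, s2.masses, 1)[0]
        assert slope2 == pytest.approx(2 * slope1, rel=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(DomainError):
            generate_desiccation_series(0.7, 0.0)

    def test_masses_non_increasing_without_noise(self):
        s = generate_desiccation_series(0.9, 4e-3, stomatal_fraction=0.2)
        assert (np.diff(s.masses) <= 0).all()


class TestParameterRecoveryUnbiased:
    """Each stream's fitter recovers its generating parameter without
    systematic bias over stochastic replicates."""

    def test_gmin_recovery_unbiased(self):
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            s = generate_desiccation_series(0.8, 4e-3, noise_sd=2e-4,
                                            stomatal_fraction=0.15, rng=rng)
            fit = fit_gmin(s)
            if fit.success:
                errors.append(fit.gmin - 0.8)
        assert abs(np.mean(errors)) < 0.02 * 0.8

    def test_p50_recovery_unbiased(self):
        pressures = np.arange(-0.5, -5.5, -0.5)
        errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            curve = generate_vulnerability_curve(-3.2, 40.0, pressures,
                                                 noise_sd=2.0, rng=rng)
            errors.append(fit_vulnerability_curve(curve).p50 + 3.2)
        assert abs(np.mean(errors)) < 0.03

    def test_isotope_line_slope_recovered(self, default_cohort):
        cfg = default_cohort.config.isotope_params
        iso = default_cohort.isotopes
        from droughtvigor.isotopes import evaporation_line
        from droughtvigor.synthetic import SPRING_DATE
        line = evaporation_line(iso, SPRING_DATE)
        assert line.slope == pytest.approx(cfg["evap_slope"]["spring"], abs=0.3)

    def test_climate_trend_recovered(self, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seasonal = seasonal_aggregate(default_cohort.climate)
        trends = seasonal_trends(seasonal, "tmean")
        mean_slope = trends["sen_slope_per_decade"].mean()
        assert mean_slope == pytest.approx(
            default_cohort.config.climate_trend, abs=0.1)

    def test_noise_free_line_fit_exact(self):
        x = np.linspace(-9, -2, 10)
        line = fit_isotope_line(x, 4.8 * x - 15.0)
        assert line.slope == pytest.approx(4.8, abs=1e-12)
        assert line.intercept == pytest.approx(-15.0, abs=1e-12)

    def test_noise_free_trend_exact(self):
        x = 10.0 + 0.025 * np.arange(60)
        assert mann_kendall(x).sen_slope == pytest.approx(0.025, abs=1e-12)


def test_every_stream_references_known_trees(default_cohort):
    ids = set(default_cohort.trees["tree_id"])
    for stream in ("ring_widths", "tracheids", "pits_stem", "pits_branch",
                   "vulnerability", "desiccation", "water_potentials", "carbon"):
        df = getattr(default_cohort, stream)
        assert set(df["tree_id"]) <= ids
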