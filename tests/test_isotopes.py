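"""Water-isotope line fitting, offsets and source-class comparisons."""

import numpy as np
import pandas as pd
import pytest

from droughtvigor.exceptions import DomainError, ValidationError
from droughtvigor.isotopes import (GLOBAL_METEORIC_LINE, compare_depth_signature,
                                   evaporation_line, fit_isotope_line,
                                   groundwater_reference, line_offset,
                                   seasonal_shift, validate_samples)
from droughtvigor.synthetic import LATE_SUMMER_DATE, SPRING_DATE


def sample_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "date", "source_class",
                                       "d18O", "d2H"])


class TestLineFit:
    def test_exact_line_recovered(self):
        x = np.array([-9.0, -7.0, -5.0, -3.0])
        line = fit_isotope_line(x, 8.0 * x + 10.0)
        assert line.slope == pytest.approx(8.0)
        assert line.intercept == pytest.approx(10.0)
        assert line.r_squared == pytest.approx(1.0)

    def test_two_points_r2_is_one(self):
        line = fit_isotope_line([-8.0, -4.0], [-55.0, -30.0])
        assert line.r_squared == 1.0
        assert line.n == 2

    def test_normal_equations_oracle(self):
        x = np.array([-9.0, -7.5, -6.0, -4.0, -2.0])
        y = np.array([-62.0, -55.5, -44.0, -33.0, -21.5])
        line = fit_isotope_line(x, y)
        # hand solution of the 2x2 normal equations
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / \
                (n * (x * x).sum() - x.sum() ** 2)
        intercept = y.mean() - slope * x.mean()
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)

    def test_vertical_line_rejected(self):
        with pytest.raises(DomainError):
            fit_isotope_line([-5.0, -5.0, -5.0], [-40.0, -35.0, -30.0])

    def test_meteoric_line_constant(self):
        assert GLOBAL_METEORIC_LINE.intercept == 8.06
        assert GLOBAL_METEORIC_LINE.slope == 7.77

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-9, -2, 12)
        y = 5.0 * x - 8.0 + rng.normal(0, 1, 12)
        a = fit_isotope_line(x, y)
        b = fit_isotope_line(x[::-1], y[::-1])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)


class TestOffsets:
    LINE = fit_isotope_line([-9.0, -3.0], [-60.0, -30.0])

    def test_point_on_line_zero(self):
        assert line_offset(-6.0, self.LINE.predict(-6.0), self.LINE) == pytest.approx(0.0)

    def test_vertical_displacement(self):
        assert line_offset(-6.0, self.LINE.predict(-6.0) + 5.0,
                           self.LINE) == pytest.approx(5.0)

    def test_d2h_shift_moves_intercept_not_contrasts(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-9, -2, 10)
        y = 5.0 * x - 8.0 + rng.normal(0, 0.5, 10)
        base = fit_isotope_line(x, y)
        shifted = fit_isotope_line(x, y + 7.0)
        assert shifted.intercept == pytest.approx(base.intercept + 7.0, abs=1e-9)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-12)
        off_a = line_offset(x, y, base)
        off_b = line_offset(x, y + 7.0, shifted)
        assert off_a == pytest.approx(off_b, abs=1e-9)

    def test_declining_trees_depart_from_summer_line(self, default_cohort):
        # the generator keeps D xylem on the stale spring line in late
        # summer, so its absolute offsets must exceed the ND ones
        iso = default_cohort.isotopes
        line = evaporation_line(iso, LATE_SUMMER_DATE)
        day = iso[iso["date"] == LATE_SUMMER_DATE]

        def mean_abs(cls):
            sel = day[day["source_class"] == cls]
            return np.abs(line_offset(sel["d18O"].to_numpy(),
                                      sel["d2H"].to_numpy(), line)).mean()

        assert mean_abs("xylem-ND") < mean_abs("xylem-D")


class TestDepthComparison:
    def _three_groups(self, means, sd=0.3, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, mu in zip(("xylem-D", "xylem-ND", "xylem-oak"), means):
            for i in range(n):
                d18 = rng.normal(mu, sd)
                rows.append((f"{cls}-{i}", "d", cls, d18, 8.06 + 7.77 * d18))
        return sample_frame(rows)

    def test_identical_classes_share_letters(self):
        df = self._three_groups([-5.0, -5.0, -5.0], sd=1e-6)
        out = compare_depth_signature(df, "d")
        letters = out["isotopes"]["d18O"]["letters"]
        assert len(set(letters.values())) == 1

    def test_separated_classes_get_distinct_letters(self):
        df = self._three_groups([-4.0, -6.0, -8.0])
        out = compare_depth_signature(df, "d")
        res = out["isotopes"]["d18O"]
        assert res["anova_p"] < 0.001
        assert len(set(res["letters"].values())) == 3
        assert res["depth_ordering_most_negative_first"][0] == "xylem-oak"

    def test_anova_matches_hand_mean_squares(self):
        rows = []
        data = {"xylem-D": [1.0, 2.0, 3.0], "xylem-ND": [2.0, 3.0, 4.0],
                "xylem-oak": [6.0, 7.0, 8.0]}
        for cls, vals in data.items():
            for i, v in enumerate(vals):
                rows.append((f"{cls}{i}", "d", cls, v, 0.0))
        out = compare_depth_signature(sample_frame(rows), "d")
        grand = np.mean([v for vals in data.values() for v in vals])
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
        ssw = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in data.values())
        f_hand = (ssb / 2) / (ssw / 6)
        assert out["isotopes"]["d18O"]["anova_f"] == pytest.approx(f_hand, abs=1e-9)

    def test_singleton_class_excluded_with_warning(self):
        df = self._three_groups([-4.0, -6.0, -8.0])
        df = df[~((df["source_class"] == "xylem-oak") &
                  (df["sample_id"] != "xylem-oak-0"))]
        with pytest.warns(UserWarning):
            out = compare_depth_signature(df, "d")
        assert "xylem-oak" not in out["isotopes"]["d18O"]["letters"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            validate_samples(sample_frame([("a", "d", "magma", -5.0, -40.0)]))


class TestSeasonalShift:
    def _season(self, d18o_by_class, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, mu in d18o_by_class.items():
            for i in range(n):
                d18 = rng.normal(mu, 0.2)
                rows.append((f"{cls}{i}", "x", cls, d18, 5 * d18 - 10))
        return sample_frame(rows)

    def test_identical_seasons_zero_shift(self):
        a = self._season({"xylem-D": -5.0}, seed=3)
        out = seasonal_shift(a, a.copy())
        assert out["delta_d18O"].iloc[0] == pytest.approx(0.0)
        assert out["delta_d2H"].iloc[0] == pytest.approx(0.0)

    def test_constructed_enrichment_recovered(self):
        a = self._season({"xylem-D": -6.0}, seed=4)
        b = a.copy()
        b["d18O"] += 2.0
        out = seasonal_shift(a, b)
        assert out["delta_d18O"].iloc[0] == pytest.approx(2.0)

    def test_propagated_se_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        a = self._season({"xylem-ND": -6.0}, n=30, seed=6)
        b = self._season({"xylem-ND": -4.0}, n=30, seed=7)
        out = seasonal_shift(a, b)
        boots = []
        va, vb = a["d18O"].to_numpy(), b["d18O"].to_numpy()
        for _ in range(2000):
            boots.append(rng.choice(vb, len(vb)).mean()
                         - rng.choice(va, len(va)).mean())
        assert out["se_d18O"].iloc[0] == pytest.approx(np.std(boots), rel=0.10)

    def test_missing_season_omitted_with_warning(self):
        a = self._season({"xylem-D": -6.0, "xylem-ND": -6.5})
        b = self._season({"xylem-D": -5.0})
        with pytest.warns(UserWarning):
            out = seasonal_shift(a, b)
        assert set(out["source_class"]) == {"xylem-D"}


def test_groundwater_reference_pools_well_and_river(default_cohort):
    ref = groundwater_reference(default_cohort.isotopes, SPRING_DATE)
    assert ref["n"] == 5  # three well + two river samples
    assert ref["d18O"] < -8.0
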