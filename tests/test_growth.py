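"""Ring-width handling: BAI reconstruction, master chronologies,
moving cross-dating correlations, rank-sum growth comparison and the
Tucson rwl round-trip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtvigor.exceptions import (InconsistentGeometryError,
                                     InsufficientOverlapError, ValidationError)
from droughtvigor.growth import (BAISeries, RingSeries, average_cores,
                                 build_master_chronology, compare_bai_by_year,
                                 compute_bai, moving_correlation,
                                 under_bark_radius)
from droughtvigor.rwl import read_rwl, write_rwl
from droughtvigor.stats import wilcoxon_rank_sum


def make_series(widths, first_year=2000, tid="t1"):
    return RingSeries(tid, first_year, np.asarray(widths, float))


class TestBAI:
    def test_two_ring_arithmetic_from_pith(self):
        # widths [2, 3] mm filling the stem to radius 5: ring areas
        # pi*2^2 and pi*(5^2 - 2^2)
        bai = compute_bai(make_series([2.0, 3.0]), outer_radius_mm=5.0)
        assert bai.bai == pytest.approx([math.pi * 4, math.pi * 21])
        assert bai.bai == pytest.approx([12.566, 65.973], abs=1e-3)

    def test_zero_width_year_contributes_zero(self):
        bai = compute_bai(make_series([1.0, 0.0, 2.0]), 10.0)
        assert bai.bai[1] == 0.0

    def test_outside_in_anchoring(self):
        bai = compute_bai(make_series([1.0, 1.0]), outer_radius_mm=10.0)
        assert bai.radii[-1] == pytest.approx(10.0)
        assert bai.radii[0] == pytest.approx(9.0)

    def test_outer_radius_smaller_than_widths_rejected(self):
        with pytest.raises(InconsistentGeometryError):
            compute_bai(make_series([3.0, 3.0]), outer_radius_mm=5.0)

    def test_negative_width_rejected(self):
        with pytest.raises(ValidationError):
            make_series([1.0, -0.5])

    @given(st.lists(st.floats(0.0, 8.0), min_size=1, max_size=60),
           st.floats(0.0, 40.0))
    @settings(max_examples=80, deadline=None)
    def test_telescoping_conservation(self, widths, slack):
        total = sum(widths)
        outer = total + slack
        bai = compute_bai(make_series(widths), outer)
        expected = math.pi * (outer ** 2 - (outer - total) ** 2)
        assert bai.total() == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_split_year_preserves_total_only(self):
        outer = 12.0
        whole = compute_bai(make_series([4.0]), outer)
        split = compute_bai(make_series([2.0, 2.0]), outer)
        assert split.total() == pytest.approx(whole.total(), rel=1e-12)
        assert split.bai[0] != pytest.approx(split.bai[1])

    def test_under_bark_radius_helper(self):
        # dbh 26 cm over bark, 15 % bark -> 110.5 mm radius
        assert under_bark_radius(26.0) == pytest.approx(110.5)
        assert under_bark_radius(26.0, bark_fraction=0.0) == pytest.approx(130.0)


class TestMasterChronology:
    def test_identical_series_reproduced(self):
        s = make_series([1.0, 2.0, 3.0])
        master, depth = build_master_chronology([s, make_series([1.0, 2.0, 3.0], tid="t2")])
        assert master.widths == pytest.approx(s.widths)
        assert (depth["depth"] == 2).all()

    def test_mirror_series_average_to_constant(self):
        master, _ = build_master_chronology(
            [make_series([1.0, 2.0, 3.0]), make_series([3.0, 2.0, 1.0], tid="t2")])
        assert master.widths == pytest.approx([2.0, 2.0, 2.0])

    def test_mean_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        mats = rng.uniform(0.1, 4.0, size=(5, 12))
        series = [make_series(row, tid=f"t{i}") for i, row in enumerate(mats)]
        master, _ = build_master_chronology(series)
        assert master.widths == pytest.approx(mats.mean(axis=0))

    def test_disjoint_series_rejected(self):
        with pytest.raises(ValidationError):
            build_master_chronology(
                [make_series([1.0], 2000), make_series([1.0], 2010, "t2")])

    def test_average_cores_two_per_tree(self):
        merged = average_cores([make_series([1.0, 3.0]), make_series([3.0, 1.0])])
        assert merged.widths == pytest.approx([2.0, 2.0])


class TestMovingCorrelation:
    def test_series_identical_to_master(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.uniform(0.2, 2.0, 40))
        out = moving_correlation(s, s, window=20)
        assert np.allclose(out["r"], 1.0)
        assert len(out) == 21

    def test_anticorrelated_series(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.2, 2.0, 30)
        s = make_series(w)
        mirrored = make_series(5.0 - w, tid="m")  # negative of master after centring
        out = moving_correlation(s, mirrored, window=20)
        assert np.allclose(out["r"], -1.0)

    def test_matches_per_window_pearson_oracle(self):
        rng = np.random.default_rng(2)
        a = make_series(rng.uniform(0.1, 3.0, 45))
        b = make_series(rng.uniform(0.1, 3.0, 45), tid="b")
        out = moving_correlation(a, b, window=20)
        for _, row in out.iterrows():
            i = int(row["start_year"]) - 2000
            expected = np.corrcoef(a.widths[i:i + 20], b.widths[i:i + 20])[0, 1]
            assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_short_overlap_raises(self):
        with pytest.raises(InsufficientOverlapError):
            moving_correlation(make_series(np.ones(10)), make_series(np.ones(10)),
                               window=20)


class TestCompareBAIByYear:
    def _group(self, values, n, tid_prefix, years=(2000, 2001)):
        out = []
        for i in range(n):
            out.append(BAISeries(f"{tid_prefix}{i}", np.array(years),
                                 np.asarray(values[i], float),
                                 np.cumsum(values[i])))
        return out

    def test_identical_groups_nothing_flagged(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(10, 50, size=(4, 2))
        res = compare_bai_by_year(self._group(vals, 4, "d"),
                                  self._group(vals, 4, "n"))
        assert (res["table"]["p"] == 1.0).all()
        assert res["significant_windows"] == []

    def test_complete_separation_extreme_w(self):
        d = self._group(np.full((15, 2), 5.0) + np.arange(15)[:, None], 15, "d")
        nd = self._group(np.full((15, 2), 500.0) + np.arange(15)[:, None], 15, "n")
        res = compare_bai_by_year(d, nd)
        assert (res["table"]["p"] < 0.001).all()
        # W (Mann-Whitney U of the first sample) hits 0 under complete separation
        assert (res["table"]["W"] == 0.0).all()

    def test_single_shared_year(self):
        d = self._group(np.array([[1.0], [2.0]]), 2, "d", years=(2000,))
        nd = self._group(np.array([[3.0], [4.0]]), 2, "n", years=(2000,))
        res = compare_bai_by_year(d, nd)
        assert len(res["table"]) == 1


class TestWilcoxonExactOracle:
    @staticmethod
    def _exact_p(x, y):
        """Exhaustive rank-sum p: enumerate every label assignment."""
        import itertools
        pooled = np.concatenate([x, y])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        n, m = len(x), len(y)
        obs = ranks[:n].sum()
        mean = n * (n + m + 1) / 2.0
        count = total = 0
        for combo in itertools.combinations(range(n + m), n):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        return count / total

    @pytest.mark.parametrize("n,m,seed", [(4, 4, 0), (5, 6, 1), (8, 8, 2), (6, 8, 3)])
    def test_p_matches_exact_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, n), rng.normal(0.5, 1, m)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(self._exact_p(x, y), abs=1e-8)


class TestRwlRoundTrip:
    @pytest.mark.parametrize("units", [0.001, 0.01])
    def test_round_trip(self, tmp_path, units):
        rng = np.random.default_rng(5)
        series = [RingSeries(f"TR{i}", 1987, rng.integers(5, 400, 25) * units)
                  for i in range(3)]
        path = tmp_path / "site.rwl"
        write_rwl(path, series, units=units)
        back = {s.tree_id: s for s in read_rwl(path)}
        for s in series:
            assert back[s.tree_id].first_year == 1987
            assert back[s.tree_id].widths == pytest.approx(s.widths, abs=units / 2)

    def test_decade_boundary_alignment(self, tmp_path):
        s = RingSeries("EDGE", 1990, np.full(20, 0.5))  # exactly two decades
        path = tmp_path / "edge.rwl"
        write_rwl(path, [s])
        (back,) = read_rwl(path)
        assert len(back.widths) == 20
        assert back.first_year == 1990
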