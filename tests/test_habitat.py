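"""Jenks breaks (oracle-checked), habitat classing, trends, reserve rules."""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from parasdm import habitat as hb
from parasdm.geodata import GridSpec, Layer

DATA = Path(__file__).resolve().parents[1] / "data"


def jenks_bruteforce(values, k):
    """Exhaustive minimiser of within-class SSD over all break placements."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    best, best_breaks = np.inf, None
    for cuts in combinations(range(1, n), k - 1):
        ssd = 0.0
        start = 0
        for c in list(cuts) + [n]:
            grp = x[start:c]
            ssd += float(((grp - grp.mean()) ** 2).sum())
            start = c
        if ssd < best - 1e-12:
            best = ssd
            best_breaks = [x[c - 1] for c in cuts]
    return best, np.array(best_breaks)


def uniform_layer(spec, values):
    return Layer(spec, np.asarray(values, float), np.ones(spec.shape, bool))


class TestJenks:
    def test_two_point_masses(self):
        breaks = hb.jenks_breaks(np.array([1, 1, 1, 9, 9, 9.0]), k=2)
        assert breaks[0] == 1.0  # upper boundary of the lower class
        assert hb.within_class_ssd(np.array([1, 1, 1, 9, 9, 9.0]), breaks) == 0.0

    def test_constant_values_rejected(self):
        with pytest.raises(hb.HabitatError):
            hb.jenks_breaks(np.full(10, 3.0), k=2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        k = int(rng.integers(2, 5))
        x = np.round(rng.uniform(0, 10, n), 3)
        if len(np.unique(x)) < k:
            x = np.arange(n, dtype=float)
        breaks = hb.jenks_breaks(x, k=k)
        oracle_ssd, _ = jenks_bruteforce(x, k)
        assert hb.within_class_ssd(x, breaks) == pytest.approx(oracle_ssd, abs=1e-9)

    def test_subsampling_kicks_in_deterministically(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 3000)
        b1 = hb.jenks_breaks(x, k=4, max_exact=1000, subsample=500, seed=5)
        b2 = hb.jenks_breaks(x, k=4, max_exact=1000, subsample=500, seed=5)
        np.testing.assert_array_equal(b1, b2)


class TestClassify:
    @pytest.fixture
    def spec(self):
        return GridSpec(0.0, 10.0, 1.0, 10, 10)

    def test_value_at_break_falls_in_lower_class(self, spec):
        breaks = np.array([0.2, 0.5, 0.8])
        vals = np.full(spec.shape, 0.5)
        cls = hb.classify(uniform_layer(spec, vals), breaks)
        assert np.all(cls.class_layer.values == hb.CLASS_CODES["LSH"])

    def test_all_below_first_break_is_ish(self, spec):
        cls = hb.classify(uniform_layer(spec, np.full(spec.shape, 0.05)),
                          np.array([0.2, 0.5, 0.8]))
        assert np.all(cls.class_layer.values == hb.CLASS_CODES["ISH"])
        assert cls.class_areas_km2["ISH"] > 0
        assert cls.class_areas_km2["HSH"] == 0.0

    def test_counts_match_histogram_oracle(self, spec):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, spec.shape)
        breaks = np.array([0.25, 0.5, 0.75])
        cls = hb.classify(uniform_layer(spec, vals), breaks)
        v = vals.ravel()
        oracle = [
            np.sum(v <= 0.25),
            np.sum((v > 0.25) & (v <= 0.5)),
            np.sum((v > 0.5) & (v <= 0.75)),
            np.sum(v > 0.75),
        ]
        got = [np.sum(cls.class_layer.values == c) for c in (1, 2, 3, 4)]
        assert got == oracle

    def test_classify_is_idempotent_on_representatives(self, spec):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, spec.shape)
        breaks = hb.jenks_breaks(vals.ravel(), k=4)
        cls = hb.classify(uniform_layer(spec, vals), breaks)
        # representative value per class (midpoint of observed class values)
        for code in (1, 2, 3, 4):
            sel = cls.class_layer.values == code
            if sel.any():
                rep = vals[sel].mean()
                again = hb.classify(uniform_layer(spec, np.full(spec.shape, rep)), breaks)
                assert np.all(again.class_layer.values == code)

    def test_area_conservation(self, spec):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, spec.shape)
        cls = hb.classify(uniform_layer(spec, vals), np.array([0.3, 0.6, 0.9]))
        from parasdm.geodata import cell_area_km2
        total = float(cell_area_km2(spec).values.sum())
        assert sum(cls.class_areas_km2.values()) == pytest.approx(total, abs=1e-6)


class TestChange:
    @pytest.fixture
    def pair(self):
        spec = GridSpec(0.0, 10.0, 1.0, 10, 10)
        rng = np.random.default_rng(1)
        cur_vals = rng.uniform(0, 1, spec.shape)
        fut_vals = np.clip(cur_vals + rng.normal(0, 0.2, spec.shape), 0, 1)
        breaks = hb.jenks_breaks(cur_vals.ravel(), k=4)
        cur = hb.classify(uniform_layer(spec, cur_vals), breaks)
        fut = hb.classify(uniform_layer(spec, fut_vals), breaks)
        return spec, cur, fut

    def test_identical_layers_zero_ratio_all_constant(self, pair):
        _, cur, _ = pair
        ratios = hb.change_ratio(cur, cur)
        assert all(r == 0 or np.isnan(r) for r in ratios.values())
        cat = hb.change_category(cur, cur)
        assert np.all(cat.values[cat.valid_mask] == 0)

    def test_hand_tallied_ratio(self):
        spec = GridSpec(0.0, 2.0, 1.0, 2, 2)
        breaks = np.array([0.25, 0.5, 0.75])
        cur = hb.classify(uniform_layer(spec, [[0.9, 0.9], [0.1, 0.1]]), breaks)
        fut = hb.classify(uniform_layer(spec, [[0.9, 0.9], [0.9, 0.1]]), breaks)
        # rows share latitude, so HSH area grows by exactly the one-cell area
        r = hb.change_ratio(cur, fut)
        a_row0 = cur.class_areas_km2["HSH"] / 2
        from parasdm.geodata import row_areas_km2
        a_row1 = row_areas_km2(spec)[1]
        assert r["HSH"] == pytest.approx(a_row1 / (2 * a_row0))
        assert r["ISH"] == pytest.approx(-0.5)

    def test_category_counts_partition_cells(self, pair):
        _, cur, fut = pair
        cat = hb.change_category(cur, fut)
        v = cat.values[cat.valid_mask]
        assert len(v) == 100
        assert np.sum(v == 0) + np.sum(v == 1) + np.sum(v == -1) == 100

    def test_mismatched_breaks_rejected(self, pair):
        spec, cur, _ = pair
        other = hb.classify(uniform_layer(spec, np.random.default_rng(0).uniform(0, 1, spec.shape)),
                            np.array([0.1, 0.2, 0.3]))
        with pytest.raises(hb.HabitatError):
            hb.change_ratio(cur, other)


class TestTrendExtremes:
    def test_single_entry_is_both_extremes(self):
        trend = hb.trend_table([("sp", "SSP126_2020-2040", {"HSH": 0.4})])
        ext = hb.trend_extremes(trend)
        row = ext.iloc[0]
        assert row["mgr"] == row["mrr"] == 0.4

    def test_synthetic_max_min_with_keys(self):
        entries = [
            ("sp", "k1", {"MSH": 0.1}), ("sp", "k2", {"MSH": -0.3}), ("sp", "k3", {"MSH": 0.8}),
        ]
        ext = hb.trend_extremes(hb.trend_table(entries)).set_index("class")
        assert ext.loc["MSH", "mgr"] == 0.8 and ext.loc["MSH", "mgr_scenario"] == "k3"
        assert ext.loc["MSH", "mrr"] == -0.3 and ext.loc["MSH", "mrr_scenario"] == "k2"


class TestHostScreening:
    def test_threshold_and_ranking(self):
        # mean similarity values around the 0.9 screening threshold with
        # univariate-novelty shares deciding the final order
        i_values = pd.DataFrame([
            {"species": s, "scenario": "current", "i": v}
            for s, v in [("h1", 0.977), ("h2", 0.973), ("h3", 0.972),
                         ("h4", 0.938), ("h5", 0.684)]
        ])
        shares = {"h2": 33.0, "h3": 19.0, "h1": 17.0, "h4": 2.1}
        ranked = hb.select_influential_hosts(i_values, shares, i_threshold=0.9)
        assert len(ranked) == 4
        assert ranked == ["h2", "h3", "h1", "h4"]

    def test_all_below_threshold_gives_empty(self):
        i_values = pd.DataFrame([{"species": "h", "scenario": "c", "i": 0.5}])
        assert hb.select_influential_hosts(i_values, {}, 0.9) == []


class TestShrinking:
    def test_all_negative_included_all_positive_excluded(self):
        entries = [("a", f"k{i}", {"HSH": -0.1}) for i in range(4)]
        entries += [("b", f"k{i}", {"HSH": 0.1}) for i in range(4)]
        shrink = hb.shrinking_classes(hb.trend_table(entries))
        assert ("a", "HSH") in shrink and ("b", "HSH") not in shrink

    def test_published_change_table_hosts(self):
        trend = pd.read_csv(DATA / "host_class_change_ratios.csv")
        shrink = hb.shrinking_classes(trend)
        assert ("K. ceratoides", "HSH") in shrink
        assert ("N. sibirica", "MSH") in shrink
        assert ("A. splendens", "HSH") not in shrink


class TestReserve:
    @pytest.fixture
    def classified_world(self):
        spec = GridSpec(0.0, 10.0, 0.5, 20, 20)
        rng = np.random.default_rng(6)
        breaks = np.array([0.25, 0.5, 0.75])
        parasite = hb.classify(uniform_layer(spec, rng.uniform(0, 1, spec.shape)), breaks)
        hosts = {
            h: hb.classify(uniform_layer(spec, rng.uniform(0, 1, spec.shape)), breaks)
            for h in ("hA", "hB")
        }
        return spec, parasite, hosts

    def test_matches_boolean_oracle(self, classified_world):
        spec, parasite, hosts = classified_world
        shrink = {("hA", "HSH"), ("hB", "MSH")}
        rmap = hb.delineate_reserve(parasite, hosts, shrink)
        oracle = (
            np.isin(parasite.class_layer.values, [3, 4])
            & (
                (hosts["hA"].class_layer.values == 4)
                | (hosts["hB"].class_layer.values == 3)
            )
        )
        np.testing.assert_array_equal(rmap.core_layer.values.astype(bool), oracle)
        from parasdm.geodata import masked_area_km2
        assert rmap.area_km2 == pytest.approx(masked_area_km2(oracle, spec))

    def test_union_rule_is_superset(self, classified_world):
        _, parasite, hosts = classified_world
        shrink = {("hA", "HSH")}
        inter = hb.delineate_reserve(parasite, hosts, shrink, rule="intersection")
        union = hb.delineate_reserve(parasite, hosts, shrink, rule="union")
        assert union.area_km2 >= inter.area_km2
        both = inter.core_layer.values.astype(bool) & ~union.core_layer.values.astype(bool)
        assert not both.any()

    def test_monotone_in_shrink_set(self, classified_world):
        _, parasite, hosts = classified_world
        small = hb.delineate_reserve(parasite, hosts, {("hA", "HSH")})
        large = hb.delineate_reserve(parasite, hosts, {("hA", "HSH"), ("hB", "MSH")})
        assert large.area_km2 >= small.area_km2

    def test_empty_shrink_set_falls_back_to_parasite_habitat(self, classified_world):
        spec, parasite, hosts = classified_world
        rmap = hb.delineate_reserve(parasite, hosts, set())
        oracle = np.isin(parasite.class_layer.values, [3, 4])
        np.testing.assert_array_equal(rmap.core_layer.values.astype(bool), oracle)

    def test_no_overlap_gives_empty_core(self):
        spec = GridSpec(0.0, 4.0, 1.0, 4, 4)
        breaks = np.array([0.25, 0.5, 0.75])
        left = np.zeros(spec.shape); left[:, :2] = 0.9
        right = np.zeros(spec.shape); right[:, 2:] = 0.9
        parasite = hb.classify(uniform_layer(spec, left), breaks)
        hosts = {"h": hb.classify(uniform_layer(spec, right), breaks)}
        rmap = hb.delineate_reserve(parasite, hosts, {("h", "HSH")})
        assert rmap.area_km2 == 0.0
        assert not rmap.core_layer.values.astype(bool).any()
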