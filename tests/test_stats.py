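import numpy as np
import pytest

import petromap as pm
from petromap.stats import (
    METRICS,
    PERCENTILES,
    TABLE_REGION_ORDER,
    distribution_export,
    distributions_to_csv,
    percentile,
    reference_percentile_table,
)
from petromap.thickness import ThicknessMap


class FakeSample:
    def __init__(self, region, clt=np.nan, ddvs=np.nan, valid=True):
        self.region = region
        self.clt = clt
        self.ddvs = ddvs
        self.valid = valid


class TestPercentile:
    def test_median_of_1_to_100_interpolates(self):
        assert percentile(np.arange(1, 101, dtype=float), 50) == pytest.approx(50.5)

    def test_single_value_any_p(self):
        for p in (1, 5, 50, 95, 99):
            assert percentile([3.7], p) == pytest.approx(3.7)

    def test_uniform_draws_p95(self, rng):
        draws = rng.uniform(0, 10, size=10_000)
        assert percentile(draws, 95) == pytest.approx(9.5, abs=0.1)

    def test_empty_and_bad_p_rejected(self):
        with pytest.raises(ValueError):
            percentile([], 50)
        with pytest.raises(ValueError):
            percentile([1.0], 0.0)
        with pytest.raises(ValueError):
            percentile([1.0], 100.0)


class TestPercentileTable:
    def test_constant_samples_give_constant_rows(self):
        samples = [FakeSample("mastoid", clt=2.0, ddvs=5.0) for _ in range(100)]
        table = pm.build_percentile_table(samples)
        for p in PERCENTILES:
            assert table.get("mastoid", "CLT", p) == pytest.approx(2.0)
            assert table.get("All", "DDVS", p) == pytest.approx(5.0)

    def test_published_table_shape(self):
        df = reference_percentile_table().to_dataframe()
        assert df.shape == (8, 8)
        assert list(df.index)[0] == "All"
        assert df.columns.nlevels == 2

    def test_rows_monotone_in_percentile(self, rng):
        samples = [FakeSample(region, clt=v, ddvs=v * 2 + 0.5)
                   for region in ("mastoid", "parietal", "retrosigmoid")
                   for v in rng.lognormal(0.5, 0.4, size=200)]
        table = pm.build_percentile_table(samples)
        for region in table.regions:
            for metric in METRICS:
                vals = [table.get(region, metric, p) for p in PERCENTILES]
                if np.all(np.isfinite(vals)):
                    assert vals == sorted(vals)

    def test_all_row_pools_not_averages(self, rng):
        a = rng.normal(2.0, 0.2, size=300)
        b = rng.normal(6.0, 0.2, size=30)
        samples = [FakeSample("mastoid", clt=v, ddvs=v) for v in a]
        samples += [FakeSample("parietal", clt=v, ddvs=v) for v in b]
        table = pm.build_percentile_table(samples)
        pooled = np.concatenate([a, b])
        for p in PERCENTILES:
            assert table.get("All", "CLT", p) == pytest.approx(percentile(pooled, p))

    def test_samples_without_named_region_still_pool_into_all(self):
        samples = [FakeSample("mastoid", clt=1.0, ddvs=2.0)] * 5
        samples += [FakeSample("unnamed_patch", clt=9.0, ddvs=9.0)] * 5
        table = pm.build_percentile_table(samples)
        assert table.get("All", "CLT", 95) > 1.0

    def test_sparse_region_flagged_insufficient(self):
        samples = [FakeSample("mastoid", clt=2.0, ddvs=5.0)]
        samples += [FakeSample("parietal", clt=v, ddvs=v) for v in (1.0, 2.0, 3.0)]
        table = pm.build_percentile_table(samples)
        assert "mastoid" in table.insufficient
        assert "parietal" not in table.insufficient

    def test_missing_metric_values_excluded(self):
        samples = [FakeSample("mastoid", clt=2.0, ddvs=np.nan)] * 10
        table = pm.build_percentile_table(samples)
        assert np.isnan(table.get("mastoid", "DDVS", 50))
        assert table.get("mastoid", "CLT", 50) == pytest.approx(2.0)

    def test_csv_export(self, tmp_path):
        table = reference_percentile_table()
        path = tmp_path / "table.csv"
        table.save_csv(path)
        text = path.read_text()
        assert "Mastoid region" in text and "9.3" in text


class TestThreadLengthRecommendation:
    def test_published_whole_roi_values(self):
        table = reference_percentile_table()
        assert pm.thread_length_recommendation(table, "All", 99) == pytest.approx(0.8)
        assert pm.thread_length_recommendation(table, "All", 95) == pytest.approx(1.1)

    def test_published_mastoid_petrous_values(self):
        table = reference_percentile_table()
        regions = ["mastoid", "petrous_pyramid"]
        assert pm.thread_length_recommendation(table, regions, 99) == pytest.approx(1.0)
        assert pm.thread_length_recommendation(table, regions, 95) == pytest.approx(1.7)

    def test_constant_table_returns_constant(self):
        samples = [FakeSample("mastoid", clt=1.0, ddvs=3.25) for _ in range(10)]
        samples += [FakeSample("parietal", clt=1.0, ddvs=3.25) for _ in range(10)]
        table = pm.build_percentile_table(samples)
        for sel in ("All", ["mastoid"], ["mastoid", "parietal"]):
            assert pm.thread_length_recommendation(table, sel, 95) == pytest.approx(3.25)

    def test_monotone_in_coverage_and_region_selection(self):
        table = reference_percentile_table()
        for regions in ("All", ["mastoid"], ["mastoid", "petrous_pyramid"]):
            assert (pm.thread_length_recommendation(table, regions, 99)
                    <= pm.thread_length_recommendation(table, regions, 95))
        # dropping the low-DDVS region cannot shorten the allowed thread
        with_low = pm.thread_length_recommendation(
            table, ["mastoid", "petrous_pyramid", "superior_temporal_surface"], 95)
        without = pm.thread_length_recommendation(table, ["mastoid", "petrous_pyramid"], 95)
        assert without >= with_low

    def test_unavailable_coverage_rejected(self):
        table = reference_percentile_table()
        with pytest.raises(ValueError, match="percentile"):
            pm.thread_length_recommendation(table, "All", 97.5)

    def test_unknown_region_rejected(self):
        table = reference_percentile_table()
        with pytest.raises(KeyError):
            pm.thread_length_recommendation(table, ["sella_turcica"], 95)


def make_map(values, spacing=1.0, extent=(0, 2, 0, 2), metric="CLT"):
    return ThicknessMap(metric, np.asarray(values, dtype=float), spacing, extent)


class TestAggregateGroupMaps:
    def test_cellwise_mean_and_min(self):
        m1 = make_map(np.full((3, 3), 2.0))
        m2 = make_map(np.full((3, 3), 4.0))
        out = pm.aggregate_group_maps([m1, m2])["all"]
        assert out.mean_map.grid == pytest.approx(np.full((3, 3), 3.0))
        assert out.min_map.grid == pytest.approx(np.full((3, 3), 2.0))
        assert np.all(out.n_contributing == 2)

    def test_cell_present_in_one_map_only(self):
        g1 = np.full((3, 3), 2.0)
        g1[0, 0] = np.nan
        m1, m2 = make_map(g1), make_map(np.full((3, 3), 4.0))
        out = pm.aggregate_group_maps([m1, m2])["all"]
        assert out.mean_map.grid[0, 0] == pytest.approx(4.0)
        assert out.min_map.grid[0, 0] == pytest.approx(4.0)
        assert out.n_contributing[0, 0] == 1

    def test_no_coverage_cell_missing(self):
        g = np.full((3, 3), 2.0)
        g[1, 1] = np.nan
        out = pm.aggregate_group_maps([make_map(g), make_map(g)])["all"]
        assert np.isnan(out.mean_map.grid[1, 1])
        assert out.n_contributing[1, 1] == 0

    def test_matches_direct_loop(self, rng):
        maps = []
        for _ in range(5):
            g = rng.uniform(0.5, 8.0, size=(4, 5))
            g[rng.random((4, 5)) < 0.2] = np.nan
            maps.append(make_map(g, extent=(0, 3, 0, 4)))
        out = pm.aggregate_group_maps(maps)["all"]
        for i in range(4):
            for j in range(5):
                vals = [m.grid[i, j] for m in maps if np.isfinite(m.grid[i, j])]
                if vals:
                    assert out.mean_map.grid[i, j] == pytest.approx(np.mean(vals))
                    assert out.min_map.grid[i, j] == pytest.approx(np.min(vals))
                else:
                    assert np.isnan(out.mean_map.grid[i, j])

    def test_permutation_invariant(self, rng):
        maps = [make_map(rng.uniform(1, 5, size=(3, 3))) for _ in range(4)]
        a = pm.aggregate_group_maps(maps)["all"]
        b = pm.aggregate_group_maps(maps[::-1])["all"]
        assert np.allclose(a.mean_map.grid, b.mean_map.grid)
        assert np.allclose(a.min_map.grid, b.min_map.grid)

    def test_min_never_exceeds_mean(self, rng):
        maps = [make_map(rng.uniform(1, 5, size=(3, 3))) for _ in range(4)]
        out = pm.aggregate_group_maps(maps)["all"]
        assert np.all(out.min_map.grid <= out.mean_map.grid + 1e-12)

    def test_by_group_partitioning(self):
        maps = [make_map(np.full((3, 3), v)) for v in (1.0, 2.0, 3.0, 4.0)]
        metas = [
            pm.SubjectMeta("s1", "left", 9, "G1"),
            pm.SubjectMeta("s2", "right", 10, "G1"),
            pm.SubjectMeta("s3", "left", 24, "G3"),
            pm.SubjectMeta("s4", "right", 24, "G3"),
        ]
        out = pm.aggregate_group_maps(maps, metas, grouping="by_group")
        assert set(out) == {"G1", "G3"}
        assert out["G1"].mean_map.grid[0, 0] == pytest.approx(1.5)
        assert out["G3"].min_map.grid[0, 0] == pytest.approx(3.0)

    def test_grid_mismatch_rejected(self):
        m1 = make_map(np.full((3, 3), 1.0))
        m2 = make_map(np.full((5, 5), 1.0), spacing=0.5)
        with pytest.raises(ValueError, match="GridSpec"):
            pm.aggregate_group_maps([m1, m2])


class TestSubjectMeta:
    def test_age_group_consistency_enforced(self):
        pm.SubjectMeta("a", "left", 13, "G2")
        with pytest.raises(ValueError, match="inconsistent"):
            pm.SubjectMeta("a", "left", 30, "G3")
        with pytest.raises(ValueError):
            pm.SubjectMeta("a", "middle", 24, "G3")
        with pytest.raises(ValueError):
            pm.SubjectMeta("a", "left", 24, "G7")


class TestDistributionExport:
    def test_single_value_group(self):
        samples = [FakeSample("mastoid", clt=2.05) for _ in range(5)]
        (rec,) = distribution_export(samples, by="region")
        assert sum(f > 0 for f in rec["freq"]) == 1
        assert rec["q25"] == rec["median"] == rec["q75"] == pytest.approx(2.05)

    def test_frequencies_normalise(self, rng):
        samples = [FakeSample(r, clt=v)
                   for r in ("mastoid", "parietal")
                   for v in rng.uniform(0.2, 4.0, size=500)]
        for rec in distribution_export(samples, by="region"):
            assert sum(rec["freq"]) == pytest.approx(1.0, abs=1e-9)
            assert rec["n"] == 500

    def test_quartiles_match_percentile_operation(self, rng):
        vals = rng.uniform(0.5, 5.0, size=400)
        samples = [FakeSample("mastoid", clt=v) for v in vals]
        (rec,) = distribution_export(samples, by="region")
        assert rec["q25"] == pytest.approx(percentile(vals, 25))
        assert rec["median"] == pytest.approx(percentile(vals, 50))
        assert rec["q75"] == pytest.approx(percentile(vals, 75))

    def test_by_subject_grouping(self, rng):
        groups = {
            "subj1": [FakeSample("mastoid", clt=v) for v in rng.uniform(1, 2, 50)],
            "subj2": [FakeSample("mastoid", clt=v) for v in rng.uniform(2, 3, 50)],
        }
        recs = distribution_export(groups, by="subject")
        assert [r["group"] for r in recs] == ["subj1", "subj2"]

    def test_long_format_csv(self, tmp_path, rng):
        samples = [FakeSample("mastoid", clt=v) for v in rng.uniform(1, 3, 100)]
        recs = distribution_export(samples, by="region")
        path = tmp_path / "dist.csv"
        distributions_to_csv(recs, path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) == {"group", "metric", "bin_lo", "bin_hi", "freq"}
        assert df["freq"].sum() == pytest.approx(1.0, abs=1e-9)


class TestPercentileProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(0.01, 50.0), min_size=1, max_size=200),
           st.floats(1.0, 99.0), st.floats(1.0, 99.0))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_monotone_in_p_and_bounded_by_extremes(self, values, p1, p2):
        lo, hi = sorted((p1, p2))
        a, b = percentile(values, lo), percentile(values, hi)
        assert a <= b + 1e-12
        assert min(values) - 1e-12 <= a and b <= max(values) + 1e-12
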