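"""Catchments, fever burden rasters, summaries and proportion CIs."""

import numpy as np
import pandas as pd
import pytest

from careseek.burden import (
    OUTSIDE,
    CatchmentSet,
    RegionTable,
    children_surface,
    delineate_catchments,
    expected_attendance,
    percentage,
    proportion_ci,
    round_half_away,
    summarize,
)
from careseek.grids import GridSpec, Raster
from careseek.traveltime import AllocationSurface, TravelTimeSurface


@pytest.fixture
def small_layers():
    """A 6x6 layered fixture: times, allocation, population, regions, prob."""
    grid = GridSpec(6, 6)
    rng = np.random.default_rng(3)
    minutes = rng.uniform(0.0, 400.0, grid.shape)
    minutes[5, 5] = np.inf
    alloc = rng.integers(0, 3, grid.shape).astype(int)
    alloc[5, 5] = -1
    pop = rng.integers(0, 500, grid.shape).astype(float)
    regions = (np.arange(36).reshape(6, 6) // 18).astype(int)  # two halves
    prob = rng.uniform(0.0, 0.76, grid.shape)
    table = RegionTable.from_mapping(
        prevalence={0: 0.2, 1: 0.1},
        under5_fraction={0: 0.15, 1: 0.18},
    )
    return dict(
        grid=grid,
        tt=TravelTimeSurface(Raster(minutes, grid)),
        alloc=AllocationSurface(Raster(alloc, grid)),
        pop=Raster(pop, grid),
        regions=Raster(regions, grid),
        prob=Raster(prob, grid),
        table=table,
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(17.55, 17.6), (-17.55, -17.6), (0.05, 0.1), (2.449, 2.4)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 1) == expected

    def test_percentage_paper_ratios(self):
        assert percentage(401, 2283) == 17.6
        assert percentage(8021, 24830) == 32.3
        assert percentage(14902, 24830) == 60.0
        assert percentage(160294, 162286) == 98.8
        assert percentage(8616, 24830) == 34.7


class TestProportionCI:
    def test_fever_prevalence_interval(self):
        # 401 fevers of 2,283 children: 17.6% [16.0, 19.1]
        p, lo, hi = proportion_ci(401, 2283)
        assert round_half_away(100 * p) == 17.6
        assert round_half_away(100 * lo) == 16.0
        assert round_half_away(100 * hi) == 19.1

    def test_zero_successes(self):
        p, lo, hi = proportion_ci(0, 50)
        assert p == 0.0 and lo == 0.0 and hi == 0.0

    def test_even_split_half_width(self):
        p, lo, hi = proportion_ci(50, 100)
        assert p == 0.5
        assert 100 * (hi - p) == pytest.approx(9.8, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 0)
        with pytest.raises(ValueError):
            proportion_ci(11, 10)


class TestCatchments:
    def test_infinite_threshold_keeps_every_reached_cell(self, small_layers):
        cs = delineate_catchments(
            small_layers["tt"], small_layers["alloc"], np.inf
        )
        reached = np.isfinite(small_layers["tt"].minutes.values)
        assert np.array_equal(cs.mask(), reached)

    def test_zero_threshold_keeps_only_facility_cells(self, small_layers):
        cs = delineate_catchments(small_layers["tt"], small_layers["alloc"], 0.0)
        zero_cells = small_layers["tt"].minutes.values == 0.0
        assert np.array_equal(cs.mask(), zero_cells)

    def test_membership_matches_per_cell_comparison(self):
        grid = GridSpec(20, 20)
        rng = np.random.default_rng(10)
        minutes = rng.uniform(0.0, 600.0, grid.shape)
        minutes[rng.uniform(size=grid.shape) < 0.05] = np.inf
        alloc = rng.integers(0, 4, grid.shape).astype(int)
        alloc[~np.isfinite(minutes)] = -1
        cs = delineate_catchments(
            TravelTimeSurface(Raster(minutes, grid)),
            AllocationSurface(Raster(alloc, grid)),
            180.0,
        )
        expected = np.where(
            np.isfinite(minutes) & (minutes <= 180.0), alloc, OUTSIDE
        )
        np.testing.assert_array_equal(cs.catchment.values, expected)

    def test_threshold_monotonicity(self, small_layers):
        sizes = [
            delineate_catchments(small_layers["tt"], small_layers["alloc"], th)
            .mask()
            .sum()
            for th in (0.0, 60.0, 180.0, 300.0, np.inf)
        ]
        assert sizes == sorted(sizes)


class TestSurfaces:
    def test_children_surface_single_region(self):
        grid = GridSpec(4, 4)
        pop = Raster(np.full(grid.shape, 625.0), grid)  # 10,000 total
        regions = Raster(np.zeros(grid.shape, dtype=int), grid)
        table = RegionTable.from_mapping({0: 0.2}, {0: 0.15})
        ch = children_surface(pop, regions, table)
        assert ch.values.sum() == pytest.approx(1500.0)

    def test_zero_fraction_gives_zero_raster(self):
        grid = GridSpec(4, 4)
        pop = Raster(np.full(grid.shape, 10.0), grid)
        regions = Raster(np.zeros(grid.shape, dtype=int), grid)
        table = RegionTable.from_mapping({0: 0.2}, {0: 0.0})
        assert np.all(children_surface(pop, regions, table).values == 0.0)

    def test_multi_region_sums(self, small_layers):
        ch = children_surface(
            small_layers["pop"], small_layers["regions"], small_layers["table"]
        )
        pop = small_layers["pop"].values
        reg = small_layers["regions"].values
        assert ch.values[reg == 0].sum() == pytest.approx(0.15 * pop[reg == 0].sum())
        assert ch.values[reg == 1].sum() == pytest.approx(0.18 * pop[reg == 1].sum())

    def test_expected_attendance_identity(self, small_layers):
        from careseek.burden import fever_surface

        ch = children_surface(
            small_layers["pop"], small_layers["regions"], small_layers["table"]
        )
        fe = fever_surface(ch, small_layers["regions"], small_layers["table"])
        att, non = expected_attendance(fe, small_layers["prob"])
        np.testing.assert_array_equal(att.values + non.values, fe.values)

    @pytest.mark.parametrize("p_const, check", [(1.0, "non"), (0.5, "equal")])
    def test_degenerate_probabilities(self, p_const, check):
        grid = GridSpec(3, 3)
        fe = Raster(np.full(grid.shape, 8.0), grid)
        prob = Raster(np.full(grid.shape, p_const), grid)
        att, non = expected_attendance(fe, prob)
        if check == "non":
            assert np.all(non.values == 0.0)
        else:
            np.testing.assert_array_equal(att.values, non.values)


def _burden_stack(small_layers):
    from careseek.burden import fever_surface

    ch = children_surface(
        small_layers["pop"], small_layers["regions"], small_layers["table"]
    )
    fe = fever_surface(ch, small_layers["regions"], small_layers["table"])
    att, _ = expected_attendance(fe, small_layers["prob"])
    return ch, fe, att


class TestSummarize:
    def test_region_strata_conserve_totals(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        df = summarize(
            ch, fe, att, strata="regions",
            regions=small_layers["regions"], table=small_layers["table"],
        )
        body = df[df["stratum"] != "Total"]
        total = df[df["stratum"] == "Total"].iloc[0]
        assert body["fever_cases"].sum() == pytest.approx(total["fever_cases"])
        assert body["children_u5"].sum() == pytest.approx(total["children_u5"])
        np.testing.assert_allclose(
            df["expected_attendees"] + df["expected_non_attendees"],
            df["fever_cases"],
        )

    def test_cumulative_time_bands_are_nested(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        df = summarize(
            ch, fe, att, strata="time-bands", band_edges=(30, 60, 120, 180),
            cumulative=True, tt=small_layers["tt"],
        )
        body = df[df["stratum"].str.startswith("<=")]
        assert body["fever_cases"].is_monotonic_increasing
        assert body["children_u5"].is_monotonic_increasing

    def test_exclusive_time_bands_partition(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        df = summarize(
            ch, fe, att, strata="time-bands", band_edges=(30, 60, 120, 180),
            cumulative=False, tt=small_layers["tt"],
        )
        body = df[df["stratum"] != "Total"]
        total = df[df["stratum"] == "Total"].iloc[0]
        assert body["fever_cases"].sum() == pytest.approx(total["fever_cases"])

    def test_probability_bands_partition(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        df = summarize(
            ch, fe, att, strata="probability-bands",
            band_edges=(0.5, 0.6, 0.7, 0.75), probability=small_layers["prob"],
        )
        body = df[df["stratum"] != "Total"]
        total = df[df["stratum"] == "Total"].iloc[0]
        assert body["children_u5"].sum() == pytest.approx(total["children_u5"])

    def test_catchment_strata_and_in_catchment_column(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        cs = delineate_catchments(small_layers["tt"], small_layers["alloc"], 180.0)
        df = summarize(ch, fe, att, strata="catchments", catchments=cs)
        total = df[df["stratum"] == "Total"].iloc[0]
        assert total["children_in_catchment"] <= total["children_u5"]
        inside = ch.values[cs.mask()].sum()
        assert total["children_in_catchment"] == pytest.approx(inside)

    def test_scaling_linearity(self, small_layers):
        ch, fe, att = _burden_stack(small_layers)
        df1 = summarize(
            ch, fe, att, strata="regions",
            regions=small_layers["regions"], table=small_layers["table"],
        )
        ch2 = Raster(2 * ch.values, ch.grid)
        fe2 = Raster(2 * fe.values, fe.grid)
        att2 = Raster(2 * att.values, att.grid)
        df2 = summarize(
            ch2, fe2, att2, strata="regions",
            regions=small_layers["regions"], table=small_layers["table"],
        )
        for col in ("children_u5", "fever_cases", "expected_attendees"):
            np.testing.assert_allclose(df2[col], 2 * df1[col])


class TestRegionTable:
    def test_csv_roundtrip(self, tmp_path, small_layers):
        t = small_layers["table"]
        t.to_csv(tmp_path / "rt.csv")
        back = RegionTable.from_csv(tmp_path / "rt.csv")
        pd.testing.assert_frame_equal(back.data, t.data)

    def test_rejects_out_of_range_proportions(self):
        with pytest.raises(ValueError):
            RegionTable.from_mapping({0: 1.5}, {0: 0.1})

    def test_rejects_ci_excluding_point(self):
        df = pd.DataFrame(
            {
                "region_id": [0], "name": ["r"], "prevalence": [0.2],
                "ci_low": [0.25], "ci_high": [0.3], "under5_fraction": [0.1],
            }
        )
        with pytest.raises(ValueError, match="CI"):
            RegionTable(df)
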