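"""Scenario grid, participation ramp, expansion, projection, contributions."""

import numpy as np
import pandas as pd
import pytest

from wetrisk import scenarios, synthgen
from wetrisk.scenarios import HRASeries, ScenarioSpec


class TestGrid:
    def test_exactly_18_distinct_combinations(self):
        grid = scenarios.scenario_grid()
        ids = [s.id for s in grid]
        assert len(grid) == 18
        assert len(set(ids)) == 18
        assert "IM-WR3-60" in ids

    def test_pairing_counts_for_contribution_analysis(self):
        grid = scenarios.scenario_grid()
        assert sum(s.management == "IM" for s in grid) == 9
        for w in ("WR1", "WR2", "WR3"):
            assert sum(s.restoration == w for s in grid) == 6
        for a in (0.2, 0.4, 0.6):
            assert sum(s.abatement == a for s in grid) == 6

    def test_expansion_rate_by_restoration(self):
        assert ScenarioSpec("NM", "WR1", 0.2).expansion_rate == 0.0
        assert ScenarioSpec("NM", "WR2", 0.2).expansion_rate == 180.0
        assert ScenarioSpec("IM", "WR3", 0.6).expansion_rate == 180.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("IM", "WR4", 0.2)
        with pytest.raises(ValueError):
            ScenarioSpec("IM", "WR1", 0.3)


class TestParticipation:
    @pytest.mark.parametrize(
        "year,expected",
        [(2020, 0.0), (2022, 0.2), (2025, 0.5), (2030, 0.75), (2035, 1.0)],
    )
    def test_ramp_anchors(self, year, expected):
        assert scenarios.participation(year) == pytest.approx(expected)

    def test_non_decreasing_and_capped(self):
        vals = [scenarios.participation(y) for y in range(2020, 2036)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0

    @pytest.mark.parametrize("year", [2019, 2036])
    def test_out_of_range(self, year):
        with pytest.raises(ValueError):
            scenarios.participation(year)


class TestEffectiveEmissions:
    def test_full_participation_60pct_abatement(self):
        assert scenarios.effective_emissions(10.0, 0.6, 2035) == pytest.approx(4.0)

    def test_zero_abatement_is_identity(self):
        assert scenarios.effective_emissions(7.0, 0.0, 2030) == pytest.approx(7.0)

    def test_2025_20pct(self):
        # participation 0.5 x abatement 0.2 -> 10% cut
        assert scenarios.effective_emissions(10.0, 0.2, 2025) == pytest.approx(9.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            scenarios.effective_emissions(-1.0, 0.2, 2025)
        with pytest.raises(ValueError):
            scenarios.effective_emissions(1.0, 1.2, 2025)


class TestExpansion:
    def test_wr1_unchanged(self, region_and_inventory):
        region, _ = region_and_inventory
        out = scenarios.expand_wetlands(region, "WR1", 2021)
        assert out.total_wetland_area == pytest.approx(region.total_wetland_area)

    def test_wr2_adds_exactly_180(self, region_and_inventory):
        region, _ = region_and_inventory
        out = scenarios.expand_wetlands(region, "WR2", 2021)
        assert out.total_wetland_area - region.total_wetland_area == pytest.approx(180.0)
        added = out.wetlands.iloc[len(region.wetlands):]
        assert (added["wclass"] == "natural").all()

    def test_cumulative_expansion_2700(self, region_and_inventory):
        region, _ = region_and_inventory
        state = region
        for year in scenarios.YEARS:
            state = scenarios.expand_wetlands(state, "WR2", year)
        assert state.total_wetland_area - region.total_wetland_area == pytest.approx(2700.0)

    def test_wr3_targets_high_risk_counties_equally(self, region_and_inventory):
        region, _ = region_and_inventory
        targets = region.counties["county_id"].iloc[:3].tolist()
        out = scenarios.expand_wetlands(region, "WR3", 2021, high_risk_counties=targets)
        added = out.wetlands.iloc[len(region.wetlands):]
        assert sorted(added["county_id"]) == sorted(targets)
        np.testing.assert_allclose(added["area_km2"], 60.0)

    def test_wr3_without_high_risk_falls_back_to_wr2(self, region_and_inventory):
        region, _ = region_and_inventory
        a = scenarios.expand_wetlands(region, "WR3", 2021, high_risk_counties=[])
        b = scenarios.expand_wetlands(region, "WR2", 2021)
        pd.testing.assert_frame_equal(
            a.wetlands.drop(columns="wetland_id"),
            b.wetlands.drop(columns="wetland_id"),
        )


@pytest.fixture(scope="module")
def projections(study, ensemble, region_and_inventory):
    region, inv = region_and_inventory
    out = {}
    for spec in (ScenarioSpec("NM", "WR1", 0.2), ScenarioSpec("IM", "WR3", 0.6)):
        out[spec.id] = scenarios.project(
            spec, region, ensemble, study["transform"], inv,
            seed=1, n_member_chains=5,
        )
    return out


class TestProject:
    def test_series_covers_2021_to_2035(self, projections):
        for s in projections.values():
            assert list(s.table["year"]) == list(range(2021, 2036))
            assert len(s.table) == 15

    def test_band_brackets_point(self, projections):
        for s in projections.values():
            t = s.table
            assert (t["band_low"] <= t["hra_km2"] + 1e-9).all()
            assert (t["hra_km2"] <= t["band_high"] + 1e-9).all()

    def test_strong_policy_dominates_weak_policy(self, projections):
        weak = projections["NM-WR1-20"].table["hra_km2"].to_numpy()
        strong = projections["IM-WR3-60"].table["hra_km2"].to_numpy()
        assert (strong <= weak + 1e-9).all()

    def test_strong_policy_trend_is_downward(self, projections):
        s = projections["IM-WR3-60"].table["hra_km2"].to_numpy()
        assert s[-1] <= s[0]
        assert np.median(s[-5:]) <= np.median(s[:5])


class TestContributionAnalysis:
    def _series(self, values_by_id):
        out = {}
        for spec in scenarios.scenario_grid():
            vals = values_by_id(spec)
            out[spec.id] = HRASeries(
                spec,
                pd.DataFrame(
                    {
                        "year": list(scenarios.YEARS),
                        "hra_km2": vals,
                        "band_low": vals,
                        "band_high": vals,
                    }
                ),
            )
        return out

    def test_identical_series_give_zero_efficiency(self):
        series = self._series(lambda spec: [100.0] * 15)
        table = scenarios.contribution_analysis(series)
        assert np.allclose(table["efficiency"], 0.0)

    def test_im_halving_gives_50pct(self):
        series = self._series(
            lambda spec: [50.0 if spec.management == "IM" else 100.0] * 15
        )
        table = scenarios.contribution_analysis(series)
        im = table[(table["measure"] == "management") & (table["level"] == "IM")]
        assert im["efficiency"].iloc[0] == pytest.approx(0.5)
        rest = table[table["measure"] != "management"]
        assert np.allclose(rest["efficiency"], 0.0)

    def test_covers_three_measure_families(self):
        series = self._series(lambda spec: [10.0] * 15)
        table = scenarios.contribution_analysis(series)
        assert set(table["measure"]) == {"management", "restoration", "abatement"}

    def test_incomplete_grid_rejected(self):
        series = self._series(lambda spec: [10.0] * 15)
        series.pop("IM-WR3-60")
        with pytest.raises(ValueError, match="incomplete"):
            scenarios.contribution_analysis(series)
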