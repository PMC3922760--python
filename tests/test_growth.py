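"""Thermal-time phenology, daily growth, mortality and flowering rules."""

import datetime as dt

import numpy as np
import pytest

import ragweedsim as r
from ragweedsim.errors import SimulationStateError


class TestThermalTime:
    @pytest.mark.parametrize("t,expected", [
        (0.9, 0.0), (-5.0, 0.0), (31.7, 30.8), (40.0, 0.0), (45.0, 0.0),
        (20.0, 19.1),
    ])
    def test_triangular_anchors(self, t, expected):
        assert r.thermal_time_increment(t) == pytest.approx(expected)

    def test_unique_maximum_at_optimum(self):
        grid = np.arange(0.0, 45.0, 0.01)
        vals = np.array([r.thermal_time_increment(t) for t in grid])
        assert grid[vals.argmax()] == pytest.approx(31.7, abs=0.01)
        assert (vals >= 0.0).all()
        outside = (grid <= 0.9) | (grid >= 40.0)
        assert np.all(vals[outside] == 0.0)


def make_plant(stage="vegetative", leaf=10.0):
    plant = r.PlantState(stage=stage)
    plant.biomass["leaf"] = leaf
    plant.lai = leaf * 0.02
    return plant


class TestDailyGrowth:
    def test_zero_transpiration_ratio_stops_growth(self):
        plant = make_plant()
        before = plant.total_biomass
        r.daily_growth(plant, radiation=20.0, transp_ratio=0.0, tmean=20.0)
        assert plant.total_biomass == before

    def test_allocation_conserves_the_increment(self):
        params = r.GrowthParams()
        plant = make_plant()
        before = plant.total_biomass
        intercepted = 20.0 * (1 - np.exp(-params.k_ext * plant.lai))
        f_temp = r.thermal_time_increment(20.0) / (31.7 - 0.9)
        expected = params.rue * intercepted * f_temp * 0.8
        r.daily_growth(plant, 20.0, 0.8, 20.0, params)
        assert plant.total_biomass - before == pytest.approx(expected)

    def test_zero_lai_intercepts_nothing(self):
        plant = r.PlantState(stage="vegetative")  # no leaves yet, lai 0
        r.daily_growth(plant, 20.0, 1.0, 20.0)
        assert plant.total_biomass == 0.0

    @pytest.mark.parametrize("stage", ["terminated", "dead"])
    def test_terminal_stages_reject_growth(self, stage):
        with pytest.raises(SimulationStateError):
            r.daily_growth(r.PlantState(stage=stage), 20.0, 1.0, 20.0)

    def test_flowering_advances_flowering_thermal_time(self):
        plant = make_plant(stage="flowering")
        r.daily_growth(plant, 20.0, 1.0, 20.0)
        assert plant.tt_since_flowering == pytest.approx(19.1)


class TestFloweringCalendar:
    def test_onset_is_first_of_august(self):
        assert not r.check_flowering_onset(dt.date(2003, 7, 31))
        assert r.check_flowering_onset(dt.date(2003, 8, 1))
        assert r.check_flowering_onset(dt.date(2003, 9, 15))

    def test_onset_is_a_calendar_date_in_leap_years(self):
        assert r.check_flowering_onset(dt.date(2004, 8, 1))
        assert not r.check_flowering_onset(dt.date(2004, 7, 31))


class TestEndOfFlowering:
    def test_thermal_time_threshold_terminates(self):
        phen = r.PhenologyParams(maturity_tt=600.0)
        assert r.check_end_of_flowering([10.0], 600.0, [1.0] * 10, phen) == "thermal_time"

    def test_frost_night_terminates(self):
        assert r.check_end_of_flowering([-1.0], 0.0, [1.0] * 10) == "frost"
        assert r.check_end_of_flowering([0.0], 0.0, [1.0] * 10) is None  # strict <

    def test_cold_spell_needs_five_days_of_history(self):
        cold = [6.9] * 4
        assert r.check_end_of_flowering(cold, 0.0, [1.0] * 10) is None
        assert r.check_end_of_flowering(cold + [6.9], 0.0, [1.0] * 10) == "cold_spell"

    def test_drought_ratio_terminates(self):
        assert r.check_end_of_flowering([10.0], 0.0, [0.09] * 10) == "drought"
        assert r.check_end_of_flowering([10.0], 0.0, [0.09] * 9) is None

    def test_same_day_collision_resolved_by_priority(self):
        phen = r.PhenologyParams(maturity_tt=600.0)
        reason = r.check_end_of_flowering([-1.0], 600.0, [0.05] * 10, phen)
        assert reason == "thermal_time"
        assert r.check_end_of_flowering([-1.0], 0.0, [0.05] * 10) == "frost"


class TestMortality:
    def test_frost_kill_is_inclusive_at_zero(self):
        assert r.check_mortality(0.0, [1.0] * 10, "vegetative") == "frost"
        assert r.check_mortality(-2.0, [1.0] * 10, "flowering") == "frost"

    def test_mild_night_is_survivable(self):
        assert r.check_mortality(0.3, [1.0] * 10, "vegetative") is None

    def test_ten_day_drought_kills(self):
        assert r.check_mortality(5.0, [0.08] * 10, "vegetative") == "drought"
        assert r.check_mortality(5.0, [0.08] * 9, "vegetative") is None


class TestStandBiomassEnvelope:
    def test_favourable_season_biomass_is_plausible(self, temperate):
        """~120 favourable days of stand growth land in a broad sanity range."""
        w = r.generate_weather(temperate, 1, seed=1)
        summer = w[(w["date"] >= "2001-04-15") & (w["date"] < "2001-08-15")]
        plant = r.PlantState(stage="vegetative")
        params = r.GrowthParams()
        density = 200.0
        mass0 = params.initial_seedling_mass * density
        for organ, frac in params.allocation_table["vegetative"].items():
            plant.biomass[organ] = mass0 * frac
        plant.lai = plant.biomass["leaf"] * params.sla
        for _, day in summer.iterrows():
            r.daily_growth(plant, day["radiation"], 1.0, day["tmean"], params)
        assert 100.0 <= plant.total_biomass <= 2000.0

    def test_cold_margin_seasons_end_earlier_than_favourable(self, archetype_runs):
        """Median season end arrives earlier under the cold archetype."""
        def median_end(name):
            _, outcomes = archetype_runs[name]
            doys = [o.season.season_end.timetuple().tm_yday
                    for o in outcomes if o.season.season_end is not None]
            return np.median(doys)

        assert median_end("boreal_cold") < median_end("temperate_favourable")
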