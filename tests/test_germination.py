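"""Dormancy release, hydrothermal germination and stochastic seed fates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ragweedsim as r
from ragweedsim.errors import ConfigurationError


class TestDormancyRelease:
    def test_rate_at_optimum_forced_by_twelve_weeks(self):
        assert r.dormancy_release_rate(4.0) == pytest.approx(1.0 / 84.0)

    @pytest.mark.parametrize("t", [-5.0, -8.0, 20.0, 25.0])
    def test_rate_zero_at_and_beyond_bounds(self, t):
        assert r.dormancy_release_rate(t) == 0.0

    def test_optimum_recovered_by_grid_scan(self):
        grid = np.arange(-2.0, 12.0 + 0.25, 0.5)
        rates = [r.dormancy_release_rate(t) for t in grid]
        assert grid[int(np.argmax(rates))] == pytest.approx(4.0)

    def test_twelve_weeks_at_optimum_completes_release(self):
        state = r.SeedBankState(old_seed=100.0)
        for _ in range(84):
            state = r.update_dormancy(state, 4.0)
        assert state.dormancy_level == pytest.approx(1.0)

    def test_eighty_three_days_is_not_enough(self):
        state = r.SeedBankState(old_seed=100.0)
        for _ in range(83):
            state = r.update_dormancy(state, 4.0)
        assert state.dormancy_level < 1.0

    def test_suboptimal_chilling_takes_longer(self):
        state = r.SeedBankState(old_seed=100.0)
        for _ in range(84):
            state = r.update_dormancy(state, 0.5)  # colder than the optimum
        assert state.dormancy_level < 1.0

    def test_time_to_release_uniquely_minimised_at_optimum(self):
        def days_to_release(t):
            rate = r.dormancy_release_rate(t)
            return math.inf if rate == 0 else math.ceil(1.0 / rate)

        grid = np.arange(-2.0, 12.0 + 0.25, 0.5)
        times = [days_to_release(t) for t in grid]
        best = min(times)
        assert grid[times.index(best)] == pytest.approx(4.0)


class TestHydrothermalTime:
    def test_no_accumulation_at_base_temperature(self):
        assert r.hydrothermal_increment(3.6, 0.0) == 0.0
        assert r.hydrothermal_increment(2.0, 0.0) == 0.0

    def test_no_accumulation_at_base_water_potential(self):
        assert r.hydrothermal_increment(13.6, -0.8) == 0.0
        assert r.hydrothermal_increment(13.6, -1.2) == 0.0

    def test_product_form_above_both_bases(self):
        assert r.hydrothermal_increment(13.6, -0.3) == pytest.approx(10.0 * 0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(t=st.floats(-10, 40), psi=st.floats(-1.5, 0))
    def test_zero_region_and_positivity(self, t, psi):
        inc = r.hydrothermal_increment(t, psi)
        if t <= 3.6 or psi <= -0.8:
            assert inc == 0.0
        else:
            assert inc > 0.0
            assert r.hydrothermal_increment(t + 1.0, psi) > inc
            assert r.hydrothermal_increment(t, min(0.0, psi + 0.1)) >= inc


class TestWeibullGermination:
    def test_zero_at_lag_phase_boundary(self):
        p = r.GerminationParams(M=95, k=0.01, a=5, c=2)
        assert r.cumulative_germination(5.0, p) == 0.0
        assert r.cumulative_germination(0.0, p) == 0.0

    def test_saturates_at_maximum_germination(self):
        p = r.GerminationParams(M=95, k=0.01, a=5, c=2)
        assert r.cumulative_germination(1e4, p) == pytest.approx(95.0)

    def test_direct_evaluation(self):
        # 95 * (1 - exp(-0.01 * (25-5)^2)) = 95 * (1 - e^-4)
        p = r.GerminationParams(M=95, k=0.01, a=5, c=2)
        expected = 95.0 * (1.0 - math.exp(-4.0))
        assert r.cumulative_germination(25.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(93.26, abs=0.01)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(M=st.floats(1, 100), k=st.floats(1e-4, 1.0), a=st.floats(0, 200),
           c=st.floats(0.2, 5.0), theta=st.floats(0, 500))
    def test_monotone_and_bounded(self, M, k, a, c, theta):
        p = r.GerminationParams(M=M, k=k, a=a, c=c)
        y = r.cumulative_germination(theta, p)
        assert 0.0 <= y <= M
        assert r.cumulative_germination(theta + 10.0, p) >= y


class TestStochasticFates:
    def test_emergence_median_is_26_percent(self):
        rng = np.random.default_rng(1)
        draws = np.array([r.draw_emergence_fraction(rng) for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(0.26, abs=0.005)
        assert draws.min() > 0.0 and draws.max() < 1.0

    def test_emergence_distribution_is_skewed(self):
        rng = np.random.default_rng(2)
        draws = np.array([r.draw_emergence_fraction(rng) for _ in range(50_000)])
        skew = ((draws - draws.mean()) ** 3).mean() / draws.std() ** 3
        assert abs(skew) > 0.1

    def test_zero_spread_degenerates_to_median(self):
        rng = np.random.default_rng(3)
        p = r.SeedFateParams(emergence_spread=0.0)
        assert all(r.draw_emergence_fraction(rng, p) == pytest.approx(0.26)
                   for _ in range(10))

    def test_predation_raw_moments(self):
        rng = np.random.default_rng(4)
        raw = np.array([r.draw_predation_loss(rng).raw for _ in range(100_000)])
        assert raw.mean() == pytest.approx(0.9, abs=3 * 0.1 / math.sqrt(len(raw)))
        assert raw.std() == pytest.approx(0.1, abs=0.002)

    def test_predation_clamped_to_unit_interval(self):
        rng = np.random.default_rng(5)
        draws = [r.draw_predation_loss(rng) for _ in range(20_000)]
        assert all(0.0 <= d.clamped <= 1.0 for d in draws)
        assert any(d.raw > 1.0 for d in draws)  # clamping is doing real work


class TestSeedbankDecay:
    def test_annual_survival_closed_form(self):
        assert r.seedbank_annual_survival(17.0) == pytest.approx(2 ** (-1 / 17))
        assert r.seedbank_annual_survival(17.0) == pytest.approx(0.9600, abs=5e-4)
        assert r.seedbank_annual_survival(1.0) == pytest.approx(0.5)

    def test_half_life_halves_the_bank_exactly(self):
        s = r.seedbank_annual_survival(17.0)
        assert s ** 17 == pytest.approx(0.5, abs=1e-12)

    def test_decay_matches_closed_form_every_year(self):
        s = r.seedbank_annual_survival(17.0)
        bank = 10_000.0
        for year in range(1, 41):
            bank *= s
            assert bank == pytest.approx(10_000.0 * 2 ** (-year / 17), rel=1e-12)

    def test_non_positive_half_life_rejected(self):
        with pytest.raises(ConfigurationError):
            r.seedbank_annual_survival(0.0)
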