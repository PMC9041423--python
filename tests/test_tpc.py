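"""Unit and property tests for the three thermal performance models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salmotherm.params import EmbryoParams, GrowthParams, HoldingParams
from salmotherm import tpc


HOLD = HoldingParams()
EMBRYO = EmbryoParams()
GROWTH = GrowthParams()


class TestHoldingMetabolism:
    @pytest.mark.parametrize(
        "T",
        [0.0, 8.0, 12.0, 16.0, 20.0],
    )
    def test_matches_direct_evaluation(self, T):
        expected = HOLD.c0 * HOLD.adult_mass_kg**HOLD.b * math.exp(HOLD.D * T)
        assert tpc.holding_metabolic_rate(T) == pytest.approx(expected, rel=1e-12)

    def test_reference_values(self):
        # direct scalar oracle: 1565.04 * 7.37**-0.217 at 0 degC,
        # times e**(0.068*16) at 16 degC, and the MJ conversion
        assert tpc.holding_metabolic_rate(0.0) == pytest.approx(1014.66, abs=0.5)
        assert tpc.holding_metabolic_rate(16.0) == pytest.approx(3011.8, abs=1.0)
        assert tpc.holding_daily_cost(16.0) == pytest.approx(0.04091, abs=2e-4)

    def test_exponential_temperature_scaling(self):
        T = np.linspace(-2, 25, 40)
        ratio = tpc.holding_metabolic_rate(T + 1) / tpc.holding_metabolic_rate(T)
        assert np.allclose(ratio, math.exp(HOLD.D))

    def test_energy_total_zero_days(self):
        assert tpc.holding_energy_total([]) == 0.0

    def test_energy_total_100_days_at_16(self):
        total = tpc.holding_energy_total(np.full(100, 16.0))
        assert total == pytest.approx(100 * tpc.holding_daily_cost(16.0), rel=1e-12)
        assert total == pytest.approx(4.091, abs=0.02)

    def test_energy_total_additive_over_concatenation(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(5, 20, 30), rng.uniform(5, 20, 17)
        assert tpc.holding_energy_total(np.concatenate([a, b])) == pytest.approx(
            tpc.holding_energy_total(a) + tpc.holding_energy_total(b)
        )

    def test_energy_total_rejects_missing_days(self):
        with pytest.raises(tpc.InsufficientDataError):
            tpc.holding_energy_total([12.0, np.nan, 14.0])

    @given(st.floats(min_value=-5, max_value=30), st.floats(min_value=0.01, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_temperature(self, T, dT):
        assert tpc.holding_metabolic_rate(T + dT) > tpc.holding_metabolic_rate(T)


class TestIncubation:
    @pytest.mark.parametrize("T,expected", [(13.0, 71), (10.0, 91)])
    def test_constant_temperature_durations(self, T, expected):
        assert tpc.incubation_duration_constant(T) == expected
        assert tpc.incubation_duration(np.full(200, T)) == expected

    @pytest.mark.parametrize("T", range(4, 21))
    def test_path_matches_closed_form(self, T):
        # oracle: ceil(1 / (0.001044*T + 0.00056)) at constant temperature
        expected = math.ceil(1.0 / (EMBRYO.dev_slope * T + EMBRYO.dev_intercept))
        assert tpc.incubation_duration(np.full(400, float(T))) == expected

    def test_warming_shortens_incubation(self):
        base = np.full(200, 9.0)
        assert tpc.incubation_duration(base * 2) <= tpc.incubation_duration(base)

    def test_exhausted_path_raises(self):
        with pytest.raises(tpc.InsufficientDataError):
            tpc.incubation_duration(np.full(10, 10.0))

    def test_cap_raises(self):
        p = EmbryoParams(max_incubation_days=30)
        with pytest.raises(tpc.InsufficientDataError):
            tpc.incubation_duration(np.full(400, 10.0), p)


class TestEmbryoMortality:
    @given(
        st.lists(st.floats(min_value=-1.0, max_value=12.0), min_size=1, max_size=120)
    )
    @settings(max_examples=60, deadline=None)
    def test_zero_mortality_at_or_below_tcrit(self, temps):
        assert tpc.embryo_mortality(np.asarray(temps)) == 0.0

    def test_constant_13_for_71_days(self):
        m = tpc.embryo_mortality(np.full(71, 13.0))
        assert m == pytest.approx(1 - math.exp(-0.024 * 71), rel=1e-12)
        assert m == pytest.approx(0.818, abs=0.001)

    def test_single_warm_day(self):
        temps = np.full(60, 12.0)
        temps[17] = 14.0
        assert tpc.embryo_mortality(temps) == pytest.approx(1 - math.exp(-0.048))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        temps = rng.uniform(8, 18, 50)
        assert tpc.embryo_mortality(temps) == pytest.approx(
            tpc.embryo_mortality(rng.permutation(temps))
        )

    def test_monotone_in_any_day(self):
        temps = np.full(40, 13.0)
        warmer = temps.copy()
        warmer[10] += 2.0
        assert tpc.embryo_mortality(warmer) > tpc.embryo_mortality(temps)

    def test_cold_days_do_not_cancel_warm_days(self):
        warm_only = tpc.embryo_mortality(np.array([15.0]))
        mixed = tpc.embryo_mortality(np.array([15.0, 2.0, 2.0]))
        assert mixed == pytest.approx(warm_only)


class TestJuvenileGrowth:
    def test_zero_at_upper_limit(self):
        assert tpc.juvenile_growth_rate(GROWTH.field_t_upper) == pytest.approx(0.0)

    def test_zero_at_lower_limit(self):
        assert tpc.juvenile_growth_rate(GROWTH.field_t_lower) == pytest.approx(0.0)

    def test_reference_value_at_16(self):
        # direct evaluation: 0.65*0.415*(19-1.833)*(1-exp(0.315*(19-24.918)))
        assert tpc.juvenile_growth_rate(16.0) == pytest.approx(3.9132, abs=1e-3)

    def test_linear_in_food(self):
        ad_lib = GrowthParams(food=1.0)
        T = np.linspace(3, 20, 25)
        assert np.allclose(
            tpc.juvenile_growth_rate(T, ad_lib) * 0.65, tpc.juvenile_growth_rate(T)
        )

    def test_negative_outside_viable_range_not_clamped(self):
        assert tpc.juvenile_growth_rate(GROWTH.field_t_upper + 2) < 0
        assert tpc.juvenile_growth_rate(GROWTH.field_t_lower - 2) < 0

    def test_optimum_rounds_to_16(self):
        assert round(tpc.optimal_growth_temperature()) == 16

    def test_optimum_without_field_correction(self):
        # dense grid-search oracle at 0.001 degC resolution
        p = GrowthParams(t_corr=0.0)
        grid = np.arange(p.field_t_lower, p.field_t_upper, 0.001)
        oracle = grid[np.argmax(tpc.juvenile_growth_rate(grid, p))]
        assert tpc.optimal_growth_temperature(p) == pytest.approx(oracle, abs=0.01)
        assert oracle == pytest.approx(19.0, abs=0.05)

    def test_optimum_invariant_to_food(self):
        lean = GrowthParams(food=0.3)
        assert tpc.optimal_growth_temperature(lean) == pytest.approx(
            tpc.optimal_growth_temperature(), abs=0.01
        )

    def test_single_interior_maximum(self):
        T = np.linspace(GROWTH.field_t_lower, GROWTH.field_t_upper, 2000)
        omega = tpc.juvenile_growth_rate(T)
        d = np.diff(omega)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
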