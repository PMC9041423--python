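"""Tests for per-pixel life-stage survival surfaces and the smolt trajectory."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from salmotherm import survival as sv
from salmotherm import tpc
from salmotherm.params import EmbryoParams, GrowthParams, HoldingParams, spring_run_budget
from salmotherm.phenology import PhenologyDist

from conftest import constant_grid

GROWTH = GrowthParams()


class TestSmoltTrajectory:
    def test_days_and_survival_at_optimum(self):
        t_opt = tpc.optimal_growth_temperature()
        days, surv = sv.grow_to_smolt(np.full(200, t_opt))
        assert days == 83
        assert surv == pytest.approx(0.592, abs=0.002)

    def test_max_smolt_survival_matches_trajectory(self):
        surv, days = sv.max_smolt_survival()
        assert (days, round(surv, 6)) == (83, pytest.approx(0.592270, abs=1e-5))

    def test_continuous_ode_oracle_within_5pct(self):
        # analytic solution of dM/dt = (Omega/100) M^(1-alpha):
        # t* = (M_s^alpha - M_1^alpha) / (alpha * Omega/100)
        for T in (12.0, 14.0, 16.0, 18.0):
            omega = tpc.juvenile_growth_rate(T)
            t_star = (
                GROWTH.smolt_mass_g**GROWTH.alpha - GROWTH.emergence_mass_g**GROWTH.alpha
            ) / (GROWTH.alpha * omega / 100.0)
            days, _ = sv.grow_to_smolt(np.full(1000, T))
            assert abs(days - t_star) / t_star < 0.05

    def test_ad_libitum_feeding_faster_and_safer(self):
        t_opt = tpc.optimal_growth_temperature()
        lean_days, lean_surv = sv.grow_to_smolt(np.full(400, t_opt))
        fed = GrowthParams(food=1.0)
        fed_days, fed_surv = sv.grow_to_smolt(np.full(400, t_opt), fed)
        assert fed_days < lean_days
        assert fed_surv > lean_surv

    def test_post_update_convention_slightly_higher(self):
        t_opt = tpc.optimal_growth_temperature()
        _, pre = sv.grow_to_smolt(np.full(200, t_opt))
        _, post = sv.grow_to_smolt(
            np.full(200, t_opt), GrowthParams(survival_mass_convention="post")
        )
        assert post > pre
        assert post == pytest.approx(0.595, abs=0.002)

    def test_path_exhaustion_raises(self):
        with pytest.raises(tpc.InsufficientDataError):
            sv.grow_to_smolt(np.full(10, 16.0))

    def test_negative_growth_never_smolts(self):
        with pytest.raises(tpc.InsufficientDataError):
            sv.grow_to_smolt(np.full(400, 23.0))


class TestHoldingLimit:
    def test_mean_spring_female_at_16C(self):
        budget = spring_run_budget()
        limit = sv.max_holding_days(16.0, budget)
        assert limit >= 100
        # 110 days of holding exceeds the spendable budget
        cost_110 = tpc.holding_energy_total(np.full(110, 16.0))
        assert budget.spendable_mean - cost_110 < 0

    def test_energy_ledger_at_peak_arrival(self):
        # zero holding days: 11.7 - 2.5 - 0.14*11.7 = 7.562 >= 3.4
        budget = spring_run_budget()
        remaining = (
            budget.initial_energy_mean * (1 - budget.gonad_fraction)
            - budget.migration_cost
        )
        assert remaining == pytest.approx(7.562)
        assert remaining >= budget.carcass_floor


def spawn_phen(mean=200.0, sd=10.0):
    return PhenologyDist("spawning", mean=mean, sd=sd)


def arrival_phen(mean=170.0, sd=10.0):
    return PhenologyDist("arrival", mean=mean, sd=sd)


class TestSpawningSurface:
    def test_requires_seed(self, grid_16c):
        with pytest.raises(ValueError):
            sv.spawning_success_surface(
                grid_16c, spawn_phen(), spring_run_budget(), seed=None
            )

    def test_monte_carlo_matches_quadrature_oracle(self, grid_16c):
        budget = spring_run_budget(n_draws=1000)
        surf = sv.spawning_success_surface(
            grid_16c, spawn_phen(), budget, seed=7, arrival_phenology=arrival_phen()
        )
        a = 169  # date index of Julian day 170 in a non-leap year
        mc = surf.values[1, a]
        # independent oracle: discretized truncated-normal spawn days x
        # closed-form success probability at each holding duration
        daily = tpc.holding_daily_cost(16.0, HoldingParams())
        z = 1.0 - norm.cdf((170 - 200) / 10.0)
        total = 0.0
        for s in range(170, 300):
            lo = max(s - 0.5, 170.0)
            p_s = (norm.cdf((s + 0.5 - 200) / 10.0) - norm.cdf((lo - 200) / 10.0)) / z
            if p_s <= 0:
                continue
            thresh = (3.4 + 2.5 + (s - 170) * daily) / 0.86
            total += p_s * norm.cdf((11.7 - thresh) / 1.0)
        assert mc == pytest.approx(100 * total, abs=3.0)

    def test_degenerate_distributions_give_0_or_100(self, grid_16c):
        budget = spring_run_budget(initial_energy_sd=1e-9, n_draws=50)
        surf = sv.spawning_success_surface(
            grid_16c,
            spawn_phen(sd=1e-9),
            budget,
            seed=3,
            arrival_phenology=arrival_phen(),
        )
        vals = surf.valid_values
        assert vals.size > 0
        assert np.all((vals == 0.0) | (vals == 100.0))

    def test_arrival_after_peak_spawns_immediately(self, grid_16c):
        surf = sv.spawning_success_surface(
            grid_16c, spawn_phen(), spring_run_budget(), seed=1,
            arrival_phenology=arrival_phen(),
        )
        # post-peak arrival: zero holding cost, mean fish has ample energy
        post_peak = 219  # Julian day 220
        assert surf.values[0, post_peak] == pytest.approx(100.0)

    def test_success_nonincreasing_in_temperature(self):
        cool = constant_grid(14.0, n_km=2)
        warm = constant_grid(16.0, n_km=2)
        kwargs = dict(
            spawn_phenology=spawn_phen(),
            budget=spring_run_budget(n_draws=300),
            seed=5,
            arrival_phenology=arrival_phen(),
        )
        s_cool = sv.spawning_success_surface(cool, **kwargs)
        s_warm = sv.spawning_success_surface(warm, **kwargs)
        both = s_cool.mask & s_warm.mask
        assert np.all(s_warm.values[both] <= s_cool.values[both] + 1e-9)

    def test_buffer_window_masks_out_of_season_pixels(self, grid_16c):
        arr = PhenologyDist("arrival", mean=170, sd=10, support_min=150, support_max=190)
        surf = sv.spawning_success_surface(
            grid_16c, spawn_phen(), spring_run_budget(n_draws=50), seed=2,
            arrival_phenology=arr, buffer_days=30,
        )
        jd = surf.dates.dayofyear.to_numpy()
        assert np.isnan(surf.values[:, jd < 120]).all()
        assert np.isfinite(surf.values[:, (jd >= 120) & (jd <= 230)]).all()


class TestEggToFrySurface:
    def test_cold_water_gives_full_survival(self):
        surf = sv.egg_to_fry_surface(constant_grid(10.0))
        vals = surf.valid_values
        assert vals.size > 0
        assert np.allclose(vals, 100.0)

    def test_constant_13_matches_closed_form(self):
        surf = sv.egg_to_fry_surface(constant_grid(13.0))
        _, expected = tpc.embryo_survival_constant(13.0)
        assert surf.values[0, 0] == pytest.approx(100 * expected, rel=1e-9)
        assert surf.values[0, 0] == pytest.approx(18.2, abs=0.1)

    def test_warmer_water_lowers_survival(self):
        v13 = sv.egg_to_fry_surface(constant_grid(13.0)).values[0, 0]
        v15 = sv.egg_to_fry_surface(constant_grid(15.0)).values[0, 0]
        assert v15 < v13

    def test_incomplete_paths_masked(self):
        surf = sv.egg_to_fry_surface(constant_grid(10.0, n_days=120))
        n = tpc.incubation_duration_constant(10.0)  # 91 days
        assert np.isfinite(surf.values[0, : 120 - n + 1]).all()
        assert np.isnan(surf.values[0, 120 - n + 1 :]).all()


class TestSmoltingSurface:
    def test_constant_optimum_scores_100(self):
        t_opt = tpc.optimal_growth_temperature()
        surf = sv.smolting_success_surface(constant_grid(t_opt))
        vals = surf.valid_values
        assert vals.size > 0
        assert np.allclose(vals, 100.0)

    def test_nonattainment_masked_by_default(self):
        surf = sv.smolting_success_surface(constant_grid(23.0))
        assert not surf.mask.any()

    def test_nonattainment_zero_when_configured(self):
        surf = sv.smolting_success_surface(constant_grid(23.0), nonattainment="zero")
        assert np.all(surf.valid_values == 0.0)

    def test_matches_scalar_trajectory(self, cool_grid):
        surf = sv.smolting_success_surface(cool_grid)
        s_max, _ = sv.max_smolt_survival()
        ki, di = 5, 100
        _, surv = sv.grow_to_smolt(cool_grid.values[ki, di:])
        assert surf.values[ki, di] == pytest.approx(100 * surv / s_max, rel=1e-9)

    def test_values_in_range_on_noisy_grid(self, cool_grid):
        for surf in (
            sv.smolting_success_surface(cool_grid),
            sv.egg_to_fry_surface(cool_grid),
        ):
            vals = surf.valid_values
            assert np.all(vals >= 0.0) and np.all(vals <= 100.0)
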