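"""Synthetic river scenarios: temperature fields, monitor records and
phenology/spatial count tables with known ground truth.

The generator emulates the structure of the real inputs the pipeline was
designed for — a dam-regulated river with a seasonal temperature cycle,
warming with distance downstream of the dam, sparse temperature monitors
with temporal gaps, and roughly Gaussian life-stage timing and position
distributions — so every downstream stage can be tested against known
parameters without field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .temperature import TemperatureGrid


class ScenarioError(ValueError):
    """An invalid synthetic-scenario configuration."""


@dataclass(frozen=True)
class RiverScenario:
    """Ground truth for a synthetic dam-regulated river.

    Temperature at river-km ``k`` (0 = confluence, ``river_length_km`` =
    dam) on date ``d``::

        mean_annual_temp
        + seasonal_amplitude * cos(2*pi*(julian(d) - peak_day)/365)
        + downstream_warming * (river_length_km - k)
        + Normal(0, daily_noise_sd)
    """

    river_length_km: int = 30
    start_date: str = "2013-01-01"
    end_date: str = "2013-12-31"
    mean_annual_temp: float = 13.0
    seasonal_amplitude: float = 6.0
    peak_day: int = 200          # Julian day of warmest water
    downstream_warming: float = 0.05  # degC per km below the dam
    daily_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.river_length_km <= 0:
            raise ScenarioError("river_length_km must be positive")
        if pd.Timestamp(self.end_date) < pd.Timestamp(self.start_date):
            raise ScenarioError("empty date range")
        if self.downstream_warming < 0:
            raise ScenarioError("downstream_warming must be >= 0")
        if self.daily_noise_sd < 0:
            raise ScenarioError("daily_noise_sd must be >= 0")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")

    @property
    def kms(self) -> np.ndarray:
        return np.arange(0, self.river_length_km + 1)


@dataclass(frozen=True)
class PopulationScenario:
    """Ground truth for a synthetic population's phenology and space use.

    Timing means/sds are Julian days (arrival of adults, spawning,
    fry emergence); spatial means/sds are river-km (redds, rearing
    juveniles). Defaults sketch a spring-run-like population: early
    arrival, long hold, autumn spawn, late-winter emergence, upstream
    spawning and rearing.
    """

    name: str = "spring"
    run_type: str = "spring"     # energy-budget preset key
    arrival_mean: float = 150.0
    arrival_sd: float = 15.0
    spawn_mean: float = 265.0
    spawn_sd: float = 12.0
    emergence_mean: float = 355.0
    emergence_sd: float = 12.0
    redd_mean_km: float = 24.0
    redd_sd_km: float = 3.0
    rearing_mean_km: float = 20.0
    rearing_sd_km: float = 5.0
    n_fish_per_survey: int = 500
    n_years: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrival_mean >= self.spawn_mean:
            raise ScenarioError("arrival_mean must precede spawn_mean")
        for label in ("arrival_sd", "spawn_sd", "emergence_sd", "redd_sd_km", "rearing_sd_km"):
            if getattr(self, label) <= 0:
                raise ScenarioError(f"{label} must be positive")
        if self.n_fish_per_survey <= 0 or self.n_years <= 0:
            raise ScenarioError("survey sizes must be positive")


def seasonal_temperature(scenario: RiverScenario, kms, julian_days) -> np.ndarray:
    """Deterministic (noise-free) component of the scenario temperature field."""
    kms = np.asarray(kms, dtype=float)[:, None]
    jd = np.asarray(julian_days, dtype=float)[None, :]
    seasonal = scenario.mean_annual_temp + scenario.seasonal_amplitude * np.cos(
        2 * np.pi * (jd - scenario.peak_day) / 365.0
    )
    gradient = scenario.downstream_warming * (scenario.river_length_km - kms)
    return seasonal + gradient


def generate_true_field(scenario: RiverScenario) -> TemperatureGrid:
    """Full (no-gap) ground-truth temperature grid for a scenario."""
    dates = scenario.dates
    values = seasonal_temperature(scenario, scenario.kms, dates.dayofyear)
    if scenario.daily_noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        values = values + rng.normal(0.0, scenario.daily_noise_sd, size=values.shape)
    return TemperatureGrid(kms=scenario.kms, dates=dates, values=values)


def sample_monitor_records(
    field: TemperatureGrid,
    monitor_kms,
    gaps: list[tuple[int, str, str]] | None = None,
) -> pd.DataFrame:
    """Extract long-format monitor records (km, date, temp_c) from a field.

    ``gaps`` lists (monitor_km, first_missing_date, last_missing_date)
    intervals whose records are omitted, emulating logger outages.
    """
    frames = []
    for km in monitor_kms:
        if km not in field.kms:
            raise ScenarioError(f"monitor km {km} outside river extent")
        row = field.values[int(km) - field.kms[0]]
        keep = np.isfinite(row)
        if gaps:
            for gkm, gstart, gend in gaps:
                if int(gkm) == int(km):
                    in_gap = (field.dates >= pd.Timestamp(gstart)) & (
                        field.dates <= pd.Timestamp(gend)
                    )
                    keep &= ~np.asarray(in_gap)
        frames.append(
            pd.DataFrame(
                {"km": int(km), "date": field.dates[keep], "temp_c": row[keep]}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["km", "date", "temp_c"])
    return pd.concat(frames, ignore_index=True)


def generate_count_table(
    mean: float,
    sd: float,
    n_obs: int,
    n_years: int,
    seed: int,
    axis: str = "day",
) -> pd.DataFrame:
    """Survey count table: per year, ``n_obs`` Normal(mean, sd) draws
    rounded to the 1-day or 1-km grid and tallied.

    Columns: ``julian_day`` (axis="day") or ``river_km`` (axis="km"),
    ``count``, ``year``. Julian days wrap into 1..365.
    """
    if n_obs <= 0:
        raise ScenarioError("n_obs must be positive")
    if sd <= 0:
        raise ScenarioError("sd must be positive")
    if axis not in ("day", "km"):
        raise ScenarioError("axis must be 'day' or 'km'")
    axis_col = "julian_day" if axis == "day" else "river_km"
    rng = np.random.default_rng(seed)
    frames = []
    for year in range(1, n_years + 1):
        draws = np.rint(rng.normal(mean, sd, size=n_obs)).astype(int)
        if axis == "day":
            draws = (draws - 1) % 365 + 1
        else:
            draws = np.clip(draws, 0, None)
        vals, counts = np.unique(draws, return_counts=True)
        frames.append(pd.DataFrame({axis_col: vals, "count": counts, "year": year}))
    return pd.concat(frames, ignore_index=True)


def population_count_tables(
    pop: PopulationScenario, river_length_km: int | None = None
) -> dict[str, pd.DataFrame]:
    """All five survey tables for a population, keyed by stage label.

    Spatial draws are clipped to the river extent when a length is given.
    """
    specs = {
        "arrival": (pop.arrival_mean, pop.arrival_sd, "day"),
        "spawning": (pop.spawn_mean, pop.spawn_sd, "day"),
        "emergence": (pop.emergence_mean, pop.emergence_sd, "day"),
        "redds": (pop.redd_mean_km, pop.redd_sd_km, "km"),
        "rearing": (pop.rearing_mean_km, pop.rearing_sd_km, "km"),
    }
    tables = {}
    for i, (stage, (mean, sd, axis)) in enumerate(specs.items()):
        table = generate_count_table(
            mean, sd, pop.n_fish_per_survey, pop.n_years, seed=pop.seed * 101 + i, axis=axis
        )
        if axis == "km" and river_length_km is not None:
            col = table["river_km"].clip(0, river_length_km)
            table = (
                table.assign(river_km=col)
                .groupby(["river_km", "year"], as_index=False)["count"]
                .sum()[["river_km", "count", "year"]]
            )
        tables[stage] = table
    return tables
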