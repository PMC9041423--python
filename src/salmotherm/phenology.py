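"""Gaussian phenology (Julian-day) and spatial (river-km) distributions.

Survey count tables are normalized per year (every year contributes equal
weight regardless of population size), fitted with weighted first and
second moments, and sampled to weight survival surfaces toward the
places and times a life stage actually occupies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DistributionError(ValueError):
    """A count table or fitted distribution that cannot be used."""


@dataclass(frozen=True)
class PhenologyDist:
    """Gaussian timing distribution for one life stage, on Julian days."""

    stage: str
    mean: float
    sd: float
    n_years: int = 1
    support_min: float | None = None  # earliest observed day
    support_max: float | None = None  # latest observed day

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DistributionError("sd must be positive")
        if not 1 <= self.mean <= 366:
            raise DistributionError("phenology mean must be a Julian day in 1..366")

    @property
    def earliest(self) -> float:
        """Earliest observed day; falls back to mean - 3 sd without data."""
        return self.support_min if self.support_min is not None else self.mean - 3 * self.sd

    @property
    def latest(self) -> float:
        return self.support_max if self.support_max is not None else self.mean + 3 * self.sd


@dataclass(frozen=True)
class SpatialDist:
    """Gaussian position distribution for one life stage, on river-km."""

    stage: str
    mean: float
    sd: float
    n_years: int = 1

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise DistributionError("sd must be positive")


@dataclass
class WeightedSample:
    """Survival values read at phenology/space-sampled pixels.

    ``n_requested`` equals the full grid pixel count (the replicate-count
    contract); draws landing off-grid or on masked pixels are dropped, so
    ``len(values) <= n_requested``.
    """

    stage: str
    population: str
    values: np.ndarray
    n_requested: int

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def retention(self) -> float:
        return self.n / self.n_requested if self.n_requested else 0.0


def normalize_counts(table: pd.DataFrame, axis_col: str | None = None) -> pd.DataFrame:
    """Convert raw counts to within-year percentages (each year sums to 100).

    Years whose total count is zero are dropped with a warning.
    """
    if axis_col is None:
        axis_col = _axis_column(table)
    table = table[[axis_col, "count", "year"]].copy()
    totals = table.groupby("year")["count"].transform("sum")
    zero_years = sorted(table.loc[totals == 0, "year"].unique())
    if zero_years:
        logger.warning("dropping years with zero total count: %s", zero_years)
        table = table[totals > 0]
        totals = totals[totals > 0]
    if table.empty:
        raise DistributionError("no usable counts after dropping empty years")
    table["pct"] = 100.0 * table["count"] / totals
    return table


def _axis_column(table: pd.DataFrame) -> str:
    for col in ("julian_day", "river_km"):
        if col in table.columns:
            return col
    raise DistributionError("count table needs a 'julian_day' or 'river_km' column")


def fit_gaussian(table: pd.DataFrame, stage: str = "unnamed"):
    """Fit a Gaussian by weighted method of moments on per-year percentages.

    Returns a :class:`PhenologyDist` for Julian-day tables and a
    :class:`SpatialDist` for river-km tables. The moments are exact for
    Gaussian data binned to the grid, up to the 1-unit discretization.
    """
    axis_col = _axis_column(table)
    pct = normalize_counts(table, axis_col)
    x = pct[axis_col].to_numpy(float)
    w = pct["pct"].to_numpy(float)
    if np.unique(x[w > 0]).size < 2:
        raise DistributionError(
            "degenerate count table (single support point); "
            "supply a fixed sd via configuration instead of fitting"
        )
    mean = float(np.average(x, weights=w))
    sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))
    n_years = int(pct["year"].nunique())
    if axis_col == "julian_day":
        return PhenologyDist(
            stage=stage,
            mean=mean,
            sd=sd,
            n_years=n_years,
            support_min=float(x[w > 0].min()),
            support_max=float(x[w > 0].max()),
        )
    return SpatialDist(stage=stage, mean=mean, sd=sd, n_years=n_years)


def julian_to_date_index(
    julian_days: np.ndarray, dates: pd.DatetimeIndex, rng: np.random.Generator
) -> np.ndarray:
    """Map Julian days onto indices of a daily date axis.

    Multi-year axes replicate the phenology across years: each draw is
    assigned a uniformly random year among those present in the axis.
    Days that do not exist on the axis map to -1.
    """
    years = dates.year.unique().to_numpy()
    chosen = rng.choice(years, size=len(julian_days))
    start = dates[0]
    origin = pd.to_datetime({"year": chosen, "month": 1, "day": 1})
    stamp = origin + pd.to_timedelta(np.asarray(julian_days) - 1, unit="D")
    idx = (stamp - start).dt.days.to_numpy().copy()
    idx[(idx < 0) | (idx >= len(dates))] = -1
    return idx


def weight_surface(surface, phen: PhenologyDist, spat: SpatialDist, seed: int) -> WeightedSample:
    """Sample a survival surface at phenology/space-distributed pixels.

    Draws (Julian day, river-km) pairs independently from the two
    Gaussians, rounds them to grid cells, drops draws that land off-grid
    or on masked pixels, and reads the surviving pixels' likelihoods.
    The number of draws equals the surface's total pixel count.
    """
    if seed is None:
        raise DistributionError("weight_surface requires an explicit seed")
    values = np.asarray(surface.values, dtype=float)
    kms = np.asarray(surface.kms)
    dates = pd.DatetimeIndex(surface.dates)
    n_req = values.size

    rng = np.random.default_rng([int(seed), 83])
    day_draws = np.rint(rng.normal(phen.mean, phen.sd, size=n_req)).astype(int)
    day_draws = (day_draws - 1) % 365 + 1
    km_draws = np.rint(rng.normal(spat.mean, spat.sd, size=n_req)).astype(int)

    di = julian_to_date_index(day_draws, dates, rng)
    ki = km_draws - int(kms[0])
    ok = (di >= 0) & (ki >= 0) & (ki < len(kms))
    picked = values[ki[ok], di[ok]]
    picked = picked[np.isfinite(picked)]
    sample = WeightedSample(
        stage=getattr(surface, "stage", phen.stage),
        population=getattr(surface, "population", ""),
        values=picked,
        n_requested=n_req,
    )
    logger.info(
        "weighted sample %s/%s: retained %d of %d draws (%.1f%%)",
        sample.stage,
        sample.population,
        sample.n,
        n_req,
        100 * sample.retention,
    )
    if sample.n < 0.01 * n_req:
        raise DistributionError(
            "fewer than 1% of phenology/space draws landed on valid pixels; "
            "the distributions do not match the grid"
        )
    return sample


def dist_summary(dist) -> dict:
    """Small serializable record of a fitted distribution."""
    out = {"stage": dist.stage, "mean": dist.mean, "sd": dist.sd, "n_years": dist.n_years}
    if isinstance(dist, PhenologyDist):
        out["support_min"] = dist.support_min
        out["support_max"] = dist.support_max
        out["axis"] = "julian_day"
    else:
        out["axis"] = "river_km"
    return out
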