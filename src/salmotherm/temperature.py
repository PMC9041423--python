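"""Build a 1 km x 1 day stream-temperature grid from sparse monitor records.

The river coordinate runs from km 0 at the confluence upstream to the dam
at the highest km. Pre-processing order: duplicate records at the same
(km, date) cell are averaged; temporal gaps shorter than 30 days are
linearly interpolated per monitor; then, per date, temperatures are
linearly interpolated in space between the monitors observing that date.
Cells upstream or downstream of every observing monitor on a date are
left missing (no extrapolation), as are unfilled temporal gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of a long-format monitor-record table.
RECORD_COLUMNS = ("km", "date", "temp_c")

MISSING_SENTINEL = -999.0


class TemperatureDataError(ValueError):
    """Monitor records or grid axes that cannot be processed."""


@dataclass
class MonitorSeries:
    """Daily temperature series at one river-km position.

    ``temps`` is aligned to ``dates`` (a daily DatetimeIndex) and may
    contain NaN for missing days.
    """

    km: float
    dates: pd.DatetimeIndex
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.km < 0:
            raise TemperatureDataError("monitor km must be >= 0")
        if len(self.dates) != len(self.temps):
            raise TemperatureDataError("dates and temps lengths differ")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise TemperatureDataError("dates must be strictly increasing")


@dataclass
class TemperatureGrid:
    """Mean daily temperature over (river-km, calendar date), NaN = no data."""

    kms: np.ndarray          # integer river-km axis, ascending
    dates: pd.DatetimeIndex  # daily axis, ascending
    values: np.ndarray       # (n_km, n_dates) degC, NaN where invalid

    def __post_init__(self) -> None:
        self.kms = np.asarray(self.kms, dtype=int)
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.kms), len(self.dates)):
            raise TemperatureDataError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.kms)}, {len(self.dates)})"
            )
        if len(self.kms) and np.any(np.diff(self.kms) != 1):
            raise TemperatureDataError("km axis must be consecutive integers")
        if len(self.dates) > 1:
            step = np.diff(self.dates.values).astype("timedelta64[D]")
            if np.any(step != np.timedelta64(1, "D")):
                raise TemperatureDataError("date axis must be consecutive days")

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask, True where a temperature is available."""
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_pixels(self) -> int:
        return self.values.size

    def valid_fraction(self) -> float:
        return float(self.mask.mean()) if self.values.size else 0.0

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (km, date, temp_c, valid), one row per cell."""
        km_col = np.repeat(self.kms, len(self.dates))
        date_col = np.tile(self.dates.values, len(self.kms))
        vals = self.values.ravel()
        return pd.DataFrame(
            {
                "km": km_col,
                "date": date_col,
                "temp_c": vals,
                "valid": np.isfinite(vals),
            }
        )

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, date_format="%Y-%m-%d")

    def to_matrix_frame(self, sentinel: float = MISSING_SENTINEL) -> pd.DataFrame:
        """Dense km-rows x date-columns matrix with a sentinel for missing cells."""
        filled = np.where(self.mask, self.values, sentinel)
        return pd.DataFrame(
            filled, index=self.kms, columns=self.dates.strftime("%Y-%m-%d")
        )

    def to_matrix_csv(self, path, sentinel: float = MISSING_SENTINEL) -> None:
        self.to_matrix_frame(sentinel).to_csv(path, index_label="km")

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "TemperatureGrid":
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"])
        kms = np.arange(frame["km"].min(), frame["km"].max() + 1)
        dates = pd.date_range(frame["date"].min(), frame["date"].max(), freq="D")
        values = np.full((len(kms), len(dates)), np.nan)
        ki = frame["km"].to_numpy(int) - kms[0]
        di = (frame["date"] - dates[0]).dt.days.to_numpy()
        temp = frame["temp_c"].to_numpy(float)
        if "valid" in frame:
            temp = np.where(frame["valid"].to_numpy(bool), temp, np.nan)
        values[ki, di] = temp
        return cls(kms=kms, dates=dates, values=values)

    @classmethod
    def from_long_csv(cls, path) -> "TemperatureGrid":
        return cls.from_long_frame(pd.read_csv(path))


def read_monitor_csv(path) -> pd.DataFrame:
    """Read a long-format monitor-record CSV (km, date, temp_c)."""
    frame = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise TemperatureDataError(f"monitor CSV missing columns: {sorted(missing)}")
    frame["date"] = pd.to_datetime(frame["date"])
    return frame[list(RECORD_COLUMNS)]


def average_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average multiple temperature recordings at the same (km, date) cell.

    Monitor km positions are first rounded to the nearest integer km
    (ties away from the confluence) so records land on the grid.
    """
    records = records.copy()
    records["date"] = pd.to_datetime(records["date"])
    # round half away from zero, i.e. away from the confluence at km 0
    km = records["km"].to_numpy(float)
    records["km"] = np.floor(km + 0.5).astype(int)
    out = (
        records.groupby(["km", "date"], as_index=False)["temp_c"]
        .mean()
        .sort_values(["km", "date"], ignore_index=True)
    )
    return out


def fill_temporal_gaps(series: MonitorSeries, max_gap_days: int = 30) -> MonitorSeries:
    """Linearly interpolate internal gaps strictly shorter than ``max_gap_days``.

    Runs of ``max_gap_days`` or more consecutive missing days, and any
    leading/trailing missing days, are left missing. Raises
    :class:`TemperatureDataError` when no day is observed at all.
    """
    temps = series.temps.copy()
    observed = np.isfinite(temps)
    if not observed.any():
        raise TemperatureDataError(f"monitor at km {series.km} has no observations")
    if observed.sum() >= 2:
        idx = np.arange(temps.size)
        obs_idx = idx[observed]
        interior = (idx > obs_idx[0]) & (idx < obs_idx[-1]) & ~observed
        if interior.any():
            # gap length = distance between flanking observations minus 1
            nxt = obs_idx[np.searchsorted(obs_idx, idx[interior], side="left")]
            prv = obs_idx[np.searchsorted(obs_idx, idx[interior], side="left") - 1]
            fillable = (nxt - prv - 1) < max_gap_days
            fill_at = idx[interior][fillable]
            temps[fill_at] = np.interp(fill_at, obs_idx, temps[obs_idx])
    return MonitorSeries(km=series.km, dates=series.dates, temps=temps)


def interpolate_spatial(
    monitors: list[MonitorSeries],
    river_length_km: int,
    dates: pd.DatetimeIndex | None = None,
) -> TemperatureGrid:
    """Linearly interpolate monitor series along the river, per date.

    For each date, cells between the outermost monitors observing that
    date get linearly interpolated temperatures; cells outside that
    bracketing range stay missing (grey / no-data), as do dates with no
    observing monitor.
    """
    if river_length_km <= 0:
        raise TemperatureDataError("river length must be positive")
    if not monitors:
        raise TemperatureDataError("need at least one monitor series")
    for m in monitors:
        if not 0 <= m.km <= river_length_km:
            raise TemperatureDataError(
                f"monitor at km {m.km} outside river extent 0..{river_length_km}"
            )

    if dates is None:
        start = min(m.dates[0] for m in monitors)
        end = max(m.dates[-1] for m in monitors)
        dates = pd.date_range(start, end, freq="D")
    kms = np.arange(0, river_length_km + 1)

    # align every monitor onto the common date axis
    mon_km = np.array([float(m.km) for m in monitors])
    order = np.argsort(mon_km)
    mon_km = mon_km[order]
    aligned = np.full((len(monitors), len(dates)), np.nan)
    for row, i in enumerate(order):
        m = monitors[i]
        pos = dates.get_indexer(m.dates)
        inside = pos >= 0
        aligned[row, pos[inside]] = m.temps[inside]

    values = np.full((len(kms), len(dates)), np.nan)
    for j in range(len(dates)):
        col = aligned[:, j]
        have = np.isfinite(col)
        if not have.any():
            continue
        xs, ys = mon_km[have], col[have]
        lo, hi = xs[0], xs[-1]
        span = (kms >= lo) & (kms <= hi)
        values[span, j] = np.interp(kms[span], xs, ys)

    grid = TemperatureGrid(kms=kms, dates=dates, values=values)
    logger.info(
        "interpolated grid %s: %.1f%% of pixels valid",
        grid.shape,
        100 * grid.valid_fraction(),
    )
    return grid


def build_grid(
    records: pd.DataFrame,
    river_length_km: int,
    max_gap_days: int = 30,
    dates: pd.DatetimeIndex | None = None,
) -> TemperatureGrid:
    """Full pre-processing chain: average duplicates, fill short temporal
    gaps per monitor, then interpolate spatially onto the 1 km x 1 day grid."""
    records = average_duplicates(records)
    if records.empty:
        raise TemperatureDataError("no monitor records supplied")
    monitors = []
    for km, group in records.groupby("km"):
        span = pd.date_range(group["date"].min(), group["date"].max(), freq="D")
        temps = np.full(len(span), np.nan)
        temps[(group["date"] - span[0]).dt.days.to_numpy()] = group["temp_c"].to_numpy()
        series = MonitorSeries(km=float(km), dates=span, temps=temps)
        monitors.append(fill_temporal_gaps(series, max_gap_days=max_gap_days))
    return interpolate_spatial(monitors, river_length_km, dates=dates)
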