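"""Per-pixel likelihood-of-success surfaces for three life stages.

Every surface shares the axes and validity mask of the input
:class:`~salmotherm.temperature.TemperatureGrid`; a pixel's date axis is
interpreted per stage (adult arrival day for spawning success, spawn day
for egg-to-fry survival, fry emergence day for smolting success), and the
value is a likelihood of surviving that stage, in percent. Pixels whose
forward temperature path is interrupted by missing data (or runs off the
grid before the stage completes) are masked NaN rather than scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .params import EmbryoParams, EnergyBudgetParams, GrowthParams, HoldingParams
from .phenology import PhenologyDist
from .temperature import TemperatureGrid
from . import tpc
from .tpc import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalSurface:
    """Likelihood of surviving one life stage, % over (river-km, date)."""

    stage: str
    population: str
    kms: np.ndarray
    dates: pd.DatetimeIndex
    values: np.ndarray  # percent in [0, 100], NaN = masked

    def __post_init__(self) -> None:
        self.kms = np.asarray(self.kms)
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("surface likelihoods must lie in [0, 100]")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_long_frame(self) -> pd.DataFrame:
        km_col = np.repeat(np.asarray(self.kms), len(self.dates))
        date_col = np.tile(self.dates.values, len(self.kms))
        vals = self.values.ravel()
        return pd.DataFrame(
            {
                "km": km_col,
                "date": date_col,
                "stage": self.stage,
                "population": self.population,
                "likelihood_pct": vals,
                "valid": np.isfinite(vals),
            }
        )

    def to_long_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False, date_format="%Y-%m-%d")


def _valid_segments(row: np.ndarray):
    """Yield (start, stop) index pairs of maximal finite runs in a row."""
    finite = np.isfinite(row)
    if not finite.any():
        return
    edges = np.flatnonzero(np.diff(finite.astype(int)))
    starts = [0] if finite[0] else []
    starts += list(edges[~finite[edges]] + 1)
    stops = list(edges[finite[edges]] + 1)
    stops += [len(row)] if finite[-1] else []
    yield from zip(starts, stops)


# ---------------------------------------------------------------------------
# Spawning success (pre-spawn holding energy budget)
# ---------------------------------------------------------------------------

def spawning_success_surface(
    grid: TemperatureGrid,
    spawn_phenology: PhenologyDist,
    budget: EnergyBudgetParams,
    hold_params: HoldingParams = HoldingParams(),
    buffer_days: int = 30,
    seed: int | None = None,
    arrival_phenology: PhenologyDist | None = None,
    population: str = "",
) -> SurvivalSurface:
    """Percent likelihood that an arriving adult survives to spawn.

    Pixel (km, date) treats the date as the adult's arrival day at that
    km. For each of ``budget.n_draws`` Monte-Carlo draws, a spawn date is
    sampled from the spawning phenology truncated at the arrival day
    (adults arriving after the phenology peak spawn immediately, at zero
    holding cost), the holding cost is summed along that km's
    temperature path, and an initial energy density is drawn; the draw
    succeeds when::

        E_I*(1 - gonad_fraction) - E_M - E_H >= E_D

    Pixels outside the arrival window ``[earliest arrival - buffer,
    latest spawn + buffer]`` (Julian days), or whose holding path crosses
    missing temperatures or the grid edge, are masked. Each pixel uses a
    deterministic random substream derived from ``seed``.
    """
    if seed is None:
        raise ValueError("spawning_success_surface requires an explicit seed")
    earliest = (arrival_phenology or spawn_phenology).earliest
    window_lo = max(1.0, earliest - buffer_days)
    window_hi = min(366.0, spawn_phenology.latest + buffer_days)
    peak = spawn_phenology.mean

    jd = grid.dates.dayofyear.to_numpy()
    in_window = (jd >= window_lo) & (jd <= window_hi)
    n_km, n_dates = grid.shape
    out = np.full((n_km, n_dates), np.nan)

    daily_cost = tpc.holding_daily_cost(grid.values, hold_params)  # NaN-preserving
    fixed = budget.migration_cost
    mu_ei, sd_ei = budget.initial_energy_mean, budget.initial_energy_sd
    keep = 1.0 - budget.gonad_fraction
    floor = budget.carcass_floor

    for ki in range(n_km):
        row_cost = daily_cost[ki]
        for seg_start, seg_stop in _valid_segments(row_cost):
            cum = np.concatenate([[0.0], np.cumsum(row_cost[seg_start:seg_stop])])
            for a in range(seg_start, seg_stop):
                if not in_window[a]:
                    continue
                rng = np.random.default_rng([int(seed), int(grid.kms[ki]), int(a)])
                jd_a = jd[a]
                if jd_a >= peak:
                    hold_cost = np.zeros(budget.n_draws)
                else:
                    # truncated-normal spawn days via inverse CDF
                    lo_p = ndtr((jd_a - peak) / spawn_phenology.sd)
                    u = rng.uniform(size=budget.n_draws)
                    s_jd = peak + spawn_phenology.sd * ndtri(lo_p + u * (1.0 - lo_p))
                    s_jd = np.maximum(np.rint(s_jd).astype(int), jd_a)
                    s_idx = a + (s_jd - jd_a)  # same-offset calendar mapping
                    if s_idx.max() >= seg_stop:
                        continue  # a holding path leaves the valid segment: mask pixel
                    hold_cost = cum[s_idx - seg_start] - cum[a - seg_start]
                e_i = rng.normal(mu_ei, sd_ei, size=budget.n_draws)
                success = e_i * keep - fixed - hold_cost >= floor
                out[ki, a] = 100.0 * success.mean()

    surface = SurvivalSurface(
        stage="spawning",
        population=population,
        kms=grid.kms,
        dates=grid.dates,
        values=out,
    )
    logger.info(
        "spawning surface (%s): window JD %.0f-%.0f, %.1f%% of pixels valid",
        population,
        window_lo,
        window_hi,
        100 * surface.mask.mean(),
    )
    return surface


def spawning_success_probability(
    hold_cost_mj: float, budget: EnergyBudgetParams
) -> float:
    """Closed-form success probability at a known holding cost.

    With E_I ~ Normal(mean, sd), success iff
    ``E_I >= (E_D + E_M + E_H) / (1 - gonad_fraction)``.
    """
    threshold = (budget.carcass_floor + budget.migration_cost + hold_cost_mj) / (
        1.0 - budget.gonad_fraction
    )
    return float(
        ndtr((budget.initial_energy_mean - threshold) / budget.initial_energy_sd)
    )


def max_holding_days(
    T: float, budget: EnergyBudgetParams, hold_params: HoldingParams = HoldingParams()
) -> int:
    """Largest whole-day holding duration a mean-energy female can afford
    at constant temperature before her remaining energy drops below the
    post-spawn floor."""
    daily = tpc.holding_daily_cost(T, hold_params)
    return int(np.floor(budget.spendable_mean / daily))


# ---------------------------------------------------------------------------
# Egg-to-fry survival
# ---------------------------------------------------------------------------

def egg_to_fry_surface(
    grid: TemperatureGrid,
    embryo_params: EmbryoParams = EmbryoParams(),
    population: str = "",
) -> SurvivalSurface:
    """Percent egg-to-fry survival for eggs spawned at each pixel.

    The incubation duration at pixel (km, date) is found by accumulating
    the daily development rate along the forward temperature path until
    it reaches 1; survival is ``100 * (1 - M_T)`` over that window.
    Pixels whose path ends (or hits ``max_incubation_days``) before
    maturation are masked.
    """
    n_km, n_dates = grid.shape
    out = np.full((n_km, n_dates), np.nan)
    for ki in range(n_km):
        row = grid.values[ki]
        for seg_start, seg_stop in _valid_segments(row):
            seg = row[seg_start:seg_stop]
            dev = np.concatenate([[0.0], np.cumsum(tpc.development_rate(seg, embryo_params))])
            haz = np.concatenate(
                [[0.0], np.cumsum(embryo_params.s_T * np.clip(seg - embryo_params.t_crit, 0, None))]
            )
            for i in range(seg.size):
                # first j >= i with cumulative development >= 1
                j = int(np.searchsorted(dev, dev[i] + 1.0, side="left")) - 1
                if j >= seg.size:
                    break  # later starts have even less development available
                if (j - i + 1) > embryo_params.max_incubation_days:
                    continue  # over the incubation cap: mask this pixel only
                out[ki, seg_start + i] = 100.0 * np.exp(-(haz[j + 1] - haz[i]))
    return SurvivalSurface(
        stage="egg_to_fry",
        population=population,
        kms=grid.kms,
        dates=grid.dates,
        values=out,
    )


# ---------------------------------------------------------------------------
# Smolting success
# ---------------------------------------------------------------------------

def grow_to_smolt(temps, p: GrowthParams = GrowthParams()):
    """Daily mass/survival trajectory from emergence to smolt size.

    ``temps[0]`` is the temperature on the emergence day (day 1, at mass
    ``emergence_mass_g``). Each day applies one growth update using that
    day's temperature and one survival decrement ``exp(-mu)``, with the
    hazard evaluated at the start-of-day mass (``"pre"`` convention) or
    the post-growth mass (``"post"``).

    Returns ``(day, survival)`` where ``day`` is the 1-based day index on
    which mass first reaches ``smolt_mass_g``. Raises
    :class:`InsufficientDataError` if the path (or ``max_rearing_days``)
    is exhausted first, or the cohort loses all mass.
    """
    temps = np.asarray(temps, dtype=float)
    mass = p.emergence_mass_g
    survival = 1.0
    day = 1
    xu, f = p.mortality_rate_1g, p.mortality_exponent
    while mass < p.smolt_mass_g:
        i = day - 1
        if i >= temps.size or day > p.max_rearing_days:
            raise InsufficientDataError("path ended before smolt size was reached")
        T = temps[i]
        if not np.isfinite(T):
            raise InsufficientDataError("missing temperature during rearing")
        new_mass = mass + tpc.juvenile_growth_rate(T, p) / 100.0 * mass ** (1 - p.alpha)
        if new_mass <= 0:
            raise InsufficientDataError("cohort lost all mass (lethal temperatures)")
        hazard_mass = mass if p.survival_mass_convention == "pre" else new_mass
        survival *= np.exp(-xu * hazard_mass**f)
        mass = new_mass
        day += 1
    return day, float(survival)


def max_smolt_survival(p: GrowthParams = GrowthParams()):
    """(absolute survival probability, days to smolt) at the thermal optimum.

    Runs the daily trajectory at the constant field temperature that
    maximizes growth; this is the normalization ceiling for
    :func:`smolting_success_surface`.
    """
    t_opt = tpc.optimal_growth_temperature(p)
    # generous constant path: smolting at the optimum takes ~3 months
    days, survival = grow_to_smolt(np.full(p.max_rearing_days, t_opt), p)
    return survival, days


def smolting_success_surface(
    grid: TemperatureGrid,
    growth_params: GrowthParams = GrowthParams(),
    population: str = "",
    nonattainment: str = "mask",
) -> SurvivalSurface:
    """Likelihood of reaching smolt size, % of the optimal-temperature maximum.

    Pixel (km, date) treats the date as a fry's emergence day at that km
    and follows the daily growth/survival trajectory along the forward
    path. The value is ``100 * S_reached / S_max`` where ``S_max`` is the
    survival of the constant-optimal-temperature trajectory. Fry whose
    path ends, loses all mass, or hits ``max_rearing_days`` before smolt
    size are masked by default (``nonattainment="mask"``) or scored 0
    (``nonattainment="zero"``).
    """
    if nonattainment not in ("mask", "zero"):
        raise ValueError("nonattainment must be 'mask' or 'zero'")
    s_max, _ = max_smolt_survival(growth_params)
    p = growth_params
    xu, f = p.mortality_rate_1g, p.mortality_exponent
    fail_value = np.nan if nonattainment == "mask" else 0.0

    n_km, n_dates = grid.shape
    out = np.full((n_km, n_dates), np.nan)
    for ki in range(n_km):
        row = grid.values[ki]
        for seg_start, seg_stop in _valid_segments(row):
            seg = row[seg_start:seg_stop]
            omega = tpc.juvenile_growth_rate(seg, p)
            n = seg.size
            mass = np.full(n, p.emergence_mass_g)
            surv = np.ones(n)
            done = np.zeros(n, dtype=bool)
            starts = np.arange(n)
            updates = np.zeros(n, dtype=int)
            for d in range(n):
                active = (starts <= d) & ~done
                if not active.any():
                    continue
                m = mass[active]
                new_m = m + omega[d] / 100.0 * m ** (1 - p.alpha)
                hz = m if p.survival_mass_convention == "pre" else new_m
                with np.errstate(invalid="ignore"):
                    surv[active] *= np.exp(-xu * np.where(new_m > 0, hz, np.nan) ** f)
                mass[active] = new_m
                updates[active] += 1
                reached = active & (mass >= p.smolt_mass_g)
                dead = active & ((mass <= 0) | ~np.isfinite(surv))
                capped = active & (updates >= p.max_rearing_days)
                out[ki, seg_start + starts[reached]] = np.clip(
                    100.0 * surv[reached] / s_max, 0.0, 100.0
                )
                out[ki, seg_start + starts[dead | (capped & ~reached)]] = fail_value
                done |= reached | dead | capped
            # starts whose path ended before completion
            unfinished = ~done
            out[ki, seg_start + starts[unfinished]] = fail_value
    return SurvivalSurface(
        stage="smolting",
        population=population,
        kms=grid.kms,
        dates=grid.dates,
        values=out,
    )
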