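"""Thermal performance models for three freshwater life stages.

Pure functions, evaluable on scalar temperatures or day-indexed
temperature paths (1-D arrays, one entry per day). Invalid temperatures
are represented as NaN; path operations refuse NaN input by raising
:class:`InsufficientDataError` so callers can mask the affected pixel.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

from .params import EmbryoParams, GrowthParams, HoldingParams


class InsufficientDataError(RuntimeError):
    """A temperature path is too short, exhausted, or contains gaps."""


def _as_path(temps) -> np.ndarray:
    path = np.asarray(temps, dtype=float)
    if path.ndim != 1 or path.size == 0:
        raise InsufficientDataError("temperature path must be a non-empty 1-D array")
    if not np.all(np.isfinite(path)):
        raise InsufficientDataError("temperature path contains missing values")
    return path


# ---------------------------------------------------------------------------
# Model 1: adult maintenance metabolism during pre-spawn holding
# ---------------------------------------------------------------------------

def holding_metabolic_rate(T, p: HoldingParams = HoldingParams()):
    """Daily maintenance metabolism ``c0 * M**b * exp(D*T)``.

    Parameters
    ----------
    T : temperature in degC (scalar or array).

    Returns
    -------
    mgO2 per day per kg, same shape as ``T``. Strictly increasing in T.
    """
    T = np.asarray(T, dtype=float)
    rate = p.c0 * p.adult_mass_kg**p.b * np.exp(p.D * T)
    return rate if rate.ndim else float(rate)


def holding_daily_cost(T, p: HoldingParams = HoldingParams()):
    """Daily holding cost in MJ per kg (metabolic rate x time step x oxycal)."""
    rate = holding_metabolic_rate(T, p)
    return rate * p.t_step_days * p.oxycal_mj_per_mgo2


def holding_energy_total(temps, p: HoldingParams = HoldingParams()) -> float:
    """Total holding cost over a day-indexed path, MJ per kg.

    A zero-length path costs nothing (arrive-and-spawn-immediately).
    Raises :class:`InsufficientDataError` if the path contains NaN.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        return 0.0
    return float(np.sum(holding_daily_cost(_as_path(temps), p)))


# ---------------------------------------------------------------------------
# Model 2: embryo maturation and temperature-dependent mortality
# ---------------------------------------------------------------------------

def development_rate(T, p: EmbryoParams = EmbryoParams()):
    """Daily embryonic development fraction, clipped at zero for cold water."""
    T = np.asarray(T, dtype=float)
    rate = np.clip(p.dev_slope * T + p.dev_intercept, 0.0, None)
    return rate if rate.ndim else float(rate)


def incubation_duration(temps, p: EmbryoParams = EmbryoParams()) -> int:
    """Days from spawning to emergence along a day-indexed path.

    Emergence occurs on the first day ``n`` at which the accumulated
    development ``sum_{i<=n} (dev_slope*T_i + dev_intercept)`` reaches 1.
    Raises :class:`InsufficientDataError` if the path (or the
    ``max_incubation_days`` cap) is exhausted first.
    """
    path = _as_path(temps)[: p.max_incubation_days]
    cum = np.cumsum(development_rate(path, p))
    idx = int(np.searchsorted(cum, 1.0, side="left"))
    if idx >= cum.size:
        raise InsufficientDataError(
            "temperature path ended before embryonic maturation completed"
        )
    return idx + 1


def incubation_duration_constant(T: float, p: EmbryoParams = EmbryoParams()) -> int:
    """Closed-form incubation duration at constant temperature: ceil(1/rate)."""
    rate = development_rate(T, p)
    if rate <= 0:
        raise InsufficientDataError(f"no development at {T} degC")
    n = math.ceil(1.0 / rate)
    if n > p.max_incubation_days:
        raise InsufficientDataError("incubation exceeds max_incubation_days")
    return n


def embryo_mortality(temps, p: EmbryoParams = EmbryoParams()) -> float:
    """Cumulative temperature-dependent embryo mortality over an incubation path.

    ``M_T = 1 - exp(-s_T * sum_i max(0, T_i - t_crit))``; exceedance below
    ``t_crit`` contributes nothing (cold days never offset warm days).
    Exactly 0 when every day is at or below ``t_crit``.
    """
    path = _as_path(temps)
    exceed = np.clip(path - p.t_crit, 0.0, None)
    return float(1.0 - np.exp(-p.s_T * exceed.sum()))


def embryo_survival_constant(T: float, p: EmbryoParams = EmbryoParams()):
    """(incubation days, egg-to-fry survival fraction) at constant temperature."""
    n = incubation_duration_constant(T, p)
    survival = 1.0 - embryo_mortality(np.full(n, float(T)), p)
    return n, survival


# ---------------------------------------------------------------------------
# Model 3: juvenile growth TPC
# ---------------------------------------------------------------------------

def juvenile_growth_rate(T, p: GrowthParams = GrowthParams()):
    """Mass-standardized specific growth rate Omega, % mass/day for a 1 g fish.

    Negative outside the viable field range ``(t_lower - t_corr,
    t_upper - t_corr)``: mass loss is returned as-is, not clamped.
    Linear in ``food``.
    """
    T = np.asarray(T, dtype=float)
    x = T + p.t_corr
    omega = p.food * p.d * (x - p.t_lower) * (1.0 - np.exp(p.g * (x - p.t_upper)))
    return omega if omega.ndim else float(omega)


def optimal_growth_temperature(p: GrowthParams = GrowthParams(), tol: float = 1e-4) -> float:
    """Field temperature maximizing the growth rate, to ``tol`` degC.

    The maximizer is independent of ``food`` (a positive scale factor);
    the search bracket is the field-scale zero-growth interval.
    """
    res = minimize_scalar(
        lambda T: -juvenile_growth_rate(T, p),
        bounds=(p.field_t_lower, p.field_t_upper),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def max_growth_rate(p: GrowthParams = GrowthParams()) -> float:
    """Growth rate at the thermal optimum, % mass/day."""
    return juvenile_growth_rate(optimal_growth_temperature(p), p)
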