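"""Parameter bundles for the three life-stage thermal performance models.

Each bundle is a frozen dataclass whose defaults are the published model
parameterizations for Chinook salmon (Oncorhynchus tshawytscha):

* :class:`HoldingParams` — maintenance metabolism of a pre-spawn adult
  holding without feeding, ``B_h = c0 * M**b * exp(D*T)`` in
  mgO2 d^-1 kg^-1.
* :class:`EmbryoParams` — temperature-dependent embryo mortality above a
  critical incubation temperature, plus the degree-day-style maturation
  rate that sets incubation duration.
* :class:`GrowthParams` — juvenile specific growth rate (Ratkowsky-type
  thermal performance curve with a field temperature correction and a
  food-limitation multiplier) and the size-dependent daily mortality
  used while growing to smolt size.
* :class:`EnergyBudgetParams` — the adult energy ledger used to score
  spawning success: initial muscle energy density, migration cost,
  gonad-formation fraction and the post-spawn carcass energy floor.

Bundles round-trip through plain dicts (``to_dict`` / ``from_dict``) so a
YAML run configuration can override any value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace


class ParameterError(ValueError):
    """An invalid model-parameter combination."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class HoldingParams:
    """Adult maintenance-metabolism model during pre-spawn holding.

    Attributes
    ----------
    c0 : daily normalization constant, mgO2 d^-1 kg^-1.
    b : mass exponent of maintenance (unitless, negative: larger fish
        spend less per kg).
    D : temperature exponent of maintenance, 1/degC.
    adult_mass_kg : adult female mass, kg.
    t_step_days : integration time step, days.
    oxycal_mj_per_mgo2 : oxycalorific conversion, MJ per mgO2.
    """

    c0: float = 1565.04
    b: float = -0.217
    D: float = 0.068
    adult_mass_kg: float = 7.37
    t_step_days: float = 1.0
    oxycal_mj_per_mgo2: float = 1.358442e-5

    def __post_init__(self) -> None:
        _check(self.c0 > 0, "c0 must be positive")
        _check(self.adult_mass_kg > 0, "adult mass must be positive")
        _check(self.oxycal_mj_per_mgo2 > 0, "oxycal conversion must be positive")
        _check(self.t_step_days > 0, "time step must be positive")


@dataclass(frozen=True)
class EmbryoParams:
    """Embryo incubation mortality and maturation-rate model.

    Daily mortality accrues at ``s_T * max(0, T - t_crit)``; development
    accrues at ``dev_slope * T + dev_intercept`` per day and the embryo
    emerges when the accumulated development reaches 1.
    """

    s_T: float = 0.024          # mortality slope, 1/(degC day)
    t_crit: float = 12.0        # no-mortality threshold, degC
    dev_slope: float = 0.001044  # 1/(degC day)
    dev_intercept: float = 0.00056  # 1/day
    max_incubation_days: int = 365

    def __post_init__(self) -> None:
        _check(self.s_T > 0, "mortality slope s_T must be positive")
        _check(self.dev_slope > 0, "development slope must be positive")
        _check(self.max_incubation_days > 0, "incubation cap must be positive")


@dataclass(frozen=True)
class GrowthParams:
    """Juvenile growth TPC, size-dependent mortality and smolt threshold.

    The mass-standardized growth rate (percent body mass per day for a
    1 g fish) is::

        Omega(T) = food * d * (T + t_corr - t_lower)
                   * (1 - exp(g * (T + t_corr - t_upper)))

    ``t_corr`` shifts the laboratory-derived curve to field conditions;
    ``food`` scales it for ration limitation (1 = ad libitum). Daily mass
    follows ``M[t+1] = M[t] + Omega/100 * M[t]**(1-alpha)`` from
    ``emergence_mass_g`` until ``smolt_mass_g``, while survival decays as
    ``exp(-mu)`` per day with ``mu = mortality_rate_1g * M**mortality_exponent``.

    ``survival_mass_convention`` selects the mass at which the daily
    hazard is evaluated: ``"pre"`` (start-of-day mass, the default) or
    ``"post"`` (mass after that day's growth).
    """

    d: float = 0.415
    g: float = 0.315
    t_lower: float = 1.833      # degC, lower zero-growth limit (lab scale)
    t_upper: float = 24.918     # degC, upper zero-growth limit (lab scale)
    t_corr: float = 3.0         # degC, lab-to-field correction
    food: float = 0.65          # fraction of maximum ration, (0, 1]
    alpha: float = 0.338        # allometric growth exponent
    emergence_mass_g: float = 0.46
    smolt_mass_g: float = 6.0
    mortality_rate_1g: float = 0.00753   # 1/day for a 1 g fish
    mortality_exponent: float = -0.27
    max_rearing_days: int = 365
    survival_mass_convention: str = "pre"

    def __post_init__(self) -> None:
        _check(self.t_lower < self.t_upper, "t_lower must be below t_upper")
        _check(0 < self.food <= 1, "food must be in (0, 1]")
        _check(
            self.smolt_mass_g > self.emergence_mass_g > 0,
            "need smolt_mass_g > emergence_mass_g > 0",
        )
        _check(
            self.survival_mass_convention in ("pre", "post"),
            "survival_mass_convention must be 'pre' or 'post'",
        )
        _check(self.max_rearing_days > 0, "rearing cap must be positive")

    @property
    def field_t_lower(self) -> float:
        """Field temperature at which growth is zero (lower limit)."""
        return self.t_lower - self.t_corr

    @property
    def field_t_upper(self) -> float:
        """Field temperature at which growth is zero (upper limit)."""
        return self.t_upper - self.t_corr


@dataclass(frozen=True)
class EnergyBudgetParams:
    """Adult energy ledger for spawning success (all MJ per kg).

    A female succeeds when initial muscle energy minus migration, holding
    and gonad costs stays at or above the post-spawn carcass floor::

        E_I - E_M - gonad_fraction*E_I - E_H  >=  E_D
    """

    initial_energy_mean: float          # E_I mean, MJ/kg
    initial_energy_sd: float = 1.0      # E_I sd, MJ/kg
    migration_cost: float = 2.0         # E_M, MJ/kg
    gonad_fraction: float = 0.14        # E_G as a fraction of the drawn E_I
    carcass_floor: float = 3.4          # E_D, MJ/kg
    n_draws: int = 1000

    def __post_init__(self) -> None:
        _check(self.initial_energy_sd > 0, "initial_energy_sd must be positive")
        _check(0 < self.gonad_fraction < 1, "gonad_fraction must be in (0, 1)")
        _check(
            self.initial_energy_mean > self.migration_cost + self.carcass_floor,
            "mean initial energy must exceed migration cost + carcass floor",
        )
        _check(self.n_draws > 0, "n_draws must be positive")

    @property
    def spendable_mean(self) -> float:
        """Mean energy available for holding after fixed costs, MJ/kg."""
        return (
            self.initial_energy_mean * (1 - self.gonad_fraction)
            - self.migration_cost
            - self.carcass_floor
        )


def spring_run_budget(**overrides) -> EnergyBudgetParams:
    """Energy budget for spring-run adults (long pre-spawn holding)."""
    kw = dict(initial_energy_mean=11.7, initial_energy_sd=1.0, migration_cost=2.5)
    kw.update(overrides)
    return EnergyBudgetParams(**kw)


def fall_run_budget(**overrides) -> EnergyBudgetParams:
    """Energy budget for fall-run adults (short holding, shorter migration)."""
    kw = dict(initial_energy_mean=8.0, initial_energy_sd=1.0, migration_cost=2.0)
    kw.update(overrides)
    return EnergyBudgetParams(**kw)


_BUDGET_PRESETS = {"spring": spring_run_budget, "fall": fall_run_budget}


def budget_preset(name: str, **overrides) -> EnergyBudgetParams:
    """Look up a named run-type energy budget ('spring' or 'fall')."""
    try:
        factory = _BUDGET_PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown budget preset {name!r}; choose from {sorted(_BUDGET_PRESETS)}"
        ) from None
    return factory(**overrides)


def to_dict(params) -> dict:
    """Serialize any parameter bundle to a plain dict."""
    return asdict(params)


def from_dict(cls, data: dict):
    """Build a bundle from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def with_overrides(params, **overrides):
    """Return a copy of a bundle with selected fields replaced."""
    return replace(params, **overrides)
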