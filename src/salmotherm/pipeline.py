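"""End-to-end driver: temperature grid -> life-stage surfaces -> weighted
comparisons, from a single structured configuration.

A run configuration (dict, or YAML via the CLI) names one river scenario,
one or more populations (each with its phenology/spatial survey scenario
and an energy-budget preset or overrides), the stages to score, and a
master seed from which every random substream is derived. The output per
population is three survival surfaces, their phenology/space-weighted
samples, and summary statistics comparing weighted against unweighted
results — the weighted-minus-unweighted mean is reported as a mitigation
index (positive when a population's observed timing and positions avoid
the thermally bad parts of the river-year).

Reintroduction scenarios are expressed by giving a population
``phenology_from: <donor name>``: the donor's fitted arrival/spawn/
emergence timing is applied to this population's river and spatial
distributions, emulating a transplanted run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phenology as ph
from . import survival as sv
from . import synthetic as syn
from . import temperature as tf
from .params import (
    EmbryoParams,
    GrowthParams,
    HoldingParams,
    budget_preset,
    from_dict,
    with_overrides,
)

logger = logging.getLogger(__name__)

STAGES = ("spawning", "egg_to_fry", "smolting")

#: phenology / spatial survey tables feeding each stage's weighting
STAGE_WEIGHTING = {
    "spawning": ("arrival", "redds"),
    "egg_to_fry": ("spawning", "redds"),
    "smolting": ("emergence", "rearing"),
}

MASK_SENTINEL = -999.0


class ConfigError(ValueError):
    """An invalid or incomplete run configuration."""


@dataclass
class ComparisonSummary:
    """Weighted vs unweighted likelihood statistics for one stage/population."""

    stage: str
    population: str
    weighted: dict
    unweighted: dict
    n_valid: int
    n_masked: int
    mitigation_index: float  # weighted mean - unweighted mean, percentage points

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PopulationResult:
    name: str
    phenology: dict          # stage -> PhenologyDist
    spatial: dict            # stage -> SpatialDist
    surfaces: dict           # stage -> SurvivalSurface
    weighted: dict           # stage -> WeightedSample
    summaries: dict          # stage -> ComparisonSummary


@dataclass
class RunResult:
    config: dict
    grid: tf.TemperatureGrid
    populations: dict = field(default_factory=dict)  # name -> PopulationResult


def _stats(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    q = np.percentile(values, [5, 25, 50, 75, 95])
    return {
        "mean": float(values.mean()),
        "p5": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "p95": float(q[4]),
        "n": int(values.size),
    }


def summarize(
    weighted: ph.WeightedSample, unweighted_values, n_masked: int = 0
) -> ComparisonSummary:
    """Summary statistics for one stage: weighted sample vs whole-grid values."""
    unweighted_values = np.asarray(unweighted_values, dtype=float)
    unweighted_values = unweighted_values[np.isfinite(unweighted_values)]
    if weighted.n == 0 or unweighted_values.size == 0:
        raise ConfigError("cannot summarize an empty sample")
    w, u = _stats(weighted.values), _stats(unweighted_values)
    return ComparisonSummary(
        stage=weighted.stage,
        population=weighted.population,
        weighted=w,
        unweighted=u,
        n_valid=u["n"],
        n_masked=int(n_masked),
        mitigation_index=w["mean"] - u["mean"],
    )


def export_heatmap_table(surface: sv.SurvivalSurface, path, sentinel: float = MASK_SENTINEL) -> None:
    """Write a dense km-rows x date-columns likelihood matrix; masked cells
    get the sentinel (never a plausible likelihood)."""
    dense = np.where(surface.mask, surface.values, sentinel)
    frame = pd.DataFrame(
        dense, index=np.asarray(surface.kms), columns=surface.dates.strftime("%Y-%m-%d")
    )
    frame.to_csv(path, index_label="km")


def read_heatmap_table(
    path, stage: str = "", population: str = "", sentinel: float = MASK_SENTINEL
) -> sv.SurvivalSurface:
    """Read a dense matrix written by :func:`export_heatmap_table`."""
    frame = pd.read_csv(path, index_col="km")
    values = frame.to_numpy(float)
    values[values == sentinel] = np.nan
    return sv.SurvivalSurface(
        stage=stage,
        population=population,
        kms=frame.index.to_numpy(int),
        dates=pd.DatetimeIndex(pd.to_datetime(frame.columns)),
        values=values,
    )


# ---------------------------------------------------------------------------
# Configuration handling
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "seed", "river", "monitors", "populations", "stages",
    "buffer_days", "n_draws", "nonattainment", "params",
}
_POP_KEYS = {"name", "run_type", "scenario", "budget", "phenology_from"}


def default_config() -> dict:
    """A complete single-population synthetic run configuration."""
    return {
        "seed": 0,
        "river": {},          # RiverScenario field overrides
        "monitors": {"spacing_km": 10, "gaps": []},
        "populations": [{"name": "spring", "run_type": "spring", "scenario": {}}],
        "stages": list(STAGES),
        "buffer_days": 30,
        "n_draws": 1000,
        "nonattainment": "mask",
        "params": {},         # holding / embryo / growth overrides
    }


def validate_config(config: dict) -> dict:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    merged = default_config()
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for key, value in config.items():
        merged[key] = value
    if not merged["populations"]:
        raise ConfigError("configuration lists no populations")
    names = set()
    for pop in merged["populations"]:
        bad = set(pop) - _POP_KEYS
        if bad:
            raise ConfigError(f"unknown population keys: {sorted(bad)}")
        if "name" not in pop:
            raise ConfigError("every population needs a name")
        if pop["name"] in names:
            raise ConfigError(f"duplicate population name {pop['name']!r}")
        names.add(pop["name"])
        donor = pop.get("phenology_from")
        if donor is not None and donor not in {p["name"] for p in merged["populations"]}:
            raise ConfigError(f"phenology_from references unknown population {donor!r}")
    bad_stages = set(merged["stages"]) - set(STAGES)
    if bad_stages:
        raise ConfigError(f"unknown stages: {sorted(bad_stages)}; choose from {STAGES}")
    bad_params = set(merged["params"]) - {"holding", "embryo", "growth"}
    if bad_params:
        raise ConfigError(f"unknown params sections: {sorted(bad_params)}")
    return merged


def _model_params(config: dict):
    overrides = config.get("params", {})
    holding = from_dict(HoldingParams, overrides.get("holding", {})) if overrides.get("holding") else HoldingParams()
    embryo = from_dict(EmbryoParams, overrides.get("embryo", {})) if overrides.get("embryo") else EmbryoParams()
    growth = from_dict(GrowthParams, overrides.get("growth", {})) if overrides.get("growth") else GrowthParams()
    return holding, embryo, growth


def _monitor_kms(monitors_cfg: dict, length_km: int) -> list[int]:
    if "kms" in monitors_cfg:
        return [int(k) for k in monitors_cfg["kms"]]
    spacing = int(monitors_cfg.get("spacing_km", 10))
    kms = list(range(0, length_km + 1, spacing))
    if kms[-1] != length_km:
        kms.append(length_km)
    return kms


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunResult:
    """Execute the full chain on a synthetic scenario.

    temperature field -> monitor records -> grid reconstruction ->
    per-population survey tables -> Gaussian fits -> survival surfaces ->
    weighted samples -> comparison summaries. All randomness derives from
    ``config['seed']``; re-running with the same configuration reproduces
    every output exactly.
    """
    config = validate_config(config)
    seed = int(config["seed"])
    holding_p, embryo_p, growth_p = _model_params(config)

    river_cfg = dict(config["river"])
    river_cfg.setdefault("seed", seed)
    scenario = syn.RiverScenario(**river_cfg)
    field_true = syn.generate_true_field(scenario)
    monitor_kms = _monitor_kms(config["monitors"], scenario.river_length_km)
    records = syn.sample_monitor_records(
        field_true, monitor_kms, gaps=config["monitors"].get("gaps") or None
    )
    grid = tf.build_grid(records, scenario.river_length_km, dates=scenario.dates)

    result = RunResult(config=config, grid=grid)

    # fit every population's own distributions first (donors for reintroduction)
    fitted: dict[str, tuple[dict, dict]] = {}
    scenarios: dict[str, syn.PopulationScenario] = {}
    for i, pop_cfg in enumerate(config["populations"]):
        name = pop_cfg["name"]
        scen_kw = dict(pop_cfg.get("scenario", {}))
        scen_kw.setdefault("seed", seed * 1000 + i)
        pop = syn.PopulationScenario(
            name=name, run_type=pop_cfg.get("run_type", "fall"), **scen_kw
        )
        scenarios[name] = pop
        tables = syn.population_count_tables(pop, scenario.river_length_km)
        phen = {s: ph.fit_gaussian(tables[s], stage=s) for s in ("arrival", "spawning", "emergence")}
        spat = {s: ph.fit_gaussian(tables[s], stage=s) for s in ("redds", "rearing")}
        fitted[name] = (phen, spat)

    for pop_cfg in config["populations"]:
        name = pop_cfg["name"]
        pop = scenarios[name]
        phen, spat = fitted[name]
        donor = pop_cfg.get("phenology_from")
        if donor:
            phen = fitted[donor][0]
            logger.info("population %s uses phenology from donor %s", name, donor)
        budget = budget_preset(pop.run_type, n_draws=int(config["n_draws"]),
                               **pop_cfg.get("budget", {}))

        surfaces, weighted, summaries = {}, {}, {}
        for stage in config["stages"]:
            if stage == "spawning":
                surf = sv.spawning_success_surface(
                    grid,
                    spawn_phenology=phen["spawning"],
                    budget=budget,
                    hold_params=holding_p,
                    buffer_days=int(config["buffer_days"]),
                    seed=seed,
                    arrival_phenology=phen["arrival"],
                    population=name,
                )
            elif stage == "egg_to_fry":
                surf = sv.egg_to_fry_surface(grid, embryo_p, population=name)
            else:
                surf = sv.smolting_success_surface(
                    grid, growth_p, population=name,
                    nonattainment=config["nonattainment"],
                )
            phen_key, spat_key = STAGE_WEIGHTING[stage]
            sample = ph.weight_surface(surf, phen[phen_key], spat[spat_key],
                                       seed=seed * 7919 + STAGES.index(stage))
            surfaces[stage] = surf
            weighted[stage] = sample
            summaries[stage] = summarize(
                sample, surf.valid_values, n_masked=int((~surf.mask).sum())
            )
        result.populations[name] = PopulationResult(
            name=name, phenology=phen, spatial=spat,
            surfaces=surfaces, weighted=weighted, summaries=summaries,
        )

    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write grid, surfaces, weighted samples, summaries and the resolved
    configuration under ``outdir`` (CSV/JSON/YAML, deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.grid.to_long_csv(outdir / "temperature_grid.csv")
    result.grid.to_matrix_csv(outdir / "temperature_matrix.csv")
    summary_doc = {}
    for name, pop in sorted(result.populations.items()):
        for stage, surf in pop.surfaces.items():
            base = f"{name}_{stage}"
            surf.to_long_csv(outdir / f"surface_{base}.csv")
            export_heatmap_table(surf, outdir / f"surface_{base}_matrix.csv")
            sample = pop.weighted[stage]
            pd.DataFrame({"likelihood_pct": sample.values}).to_csv(
                outdir / f"weighted_{base}.csv", index=False
            )
            summary_doc[base] = pop.summaries[stage].to_dict()
        summary_doc[f"{name}_distributions"] = {
            key: ph.dist_summary(d)
            for key, d in {**pop.phenology, **pop.spatial}.items()
        }
    (outdir / "summary.json").write_text(json.dumps(summary_doc, indent=2, sort_keys=True))
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(result.config, sort_keys=True))


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    return validate_config(raw)


def reintroduction_config(host: dict, donor_population: dict, host_population_name: str) -> dict:
    """Build a reintroduction run: a donor population's phenology applied to
    a host river and the host population's spatial distributions.

    ``host`` is a full run configuration containing the resident
    population ``host_population_name``; ``donor_population`` is a
    population entry (name, run_type, scenario) from another river's
    configuration. The returned configuration carries both populations,
    with a synthetic transplant population that inherits the host's
    spatial survey scenario and the donor's fitted timing.
    """
    host = validate_config(host)
    host_pop = next(
        p for p in host["populations"] if p["name"] == host_population_name
    )
    transplant_scenario = dict(host_pop.get("scenario", {}))
    for key in ("arrival_mean", "arrival_sd", "spawn_mean", "spawn_sd",
                "emergence_mean", "emergence_sd"):
        if key in donor_population.get("scenario", {}):
            transplant_scenario[key] = donor_population["scenario"][key]
    donor_entry = {
        "name": donor_population["name"],
        "run_type": donor_population.get("run_type", "spring"),
        "scenario": dict(donor_population.get("scenario", {})),
    }
    transplant = {
        "name": f"{donor_population['name']}_reintroduced",
        "run_type": donor_population.get("run_type", "spring"),
        "scenario": transplant_scenario,
        "phenology_from": donor_population["name"],
    }
    host["populations"] = list(host["populations"]) + [donor_entry, transplant]
    return host
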