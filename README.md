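# salmotherm

Temperature-dependent survival of freshwater Chinook salmon
(*Oncorhynchus tshawytscha*) life stages, resolved on a 1 river-km × 1 day
grid.

Water temperature is the dominant abiotic control on the freshwater
survival of Pacific salmon, and in dam-regulated rivers managers can move
it — by releasing more or colder reservoir water, or shifting release
timing. But a single binary temperature threshold cannot say *which* life
stage loses the most when a river runs warm, because the thermal
performance curves of pre-spawn adults, incubating embryos and
stream-rearing juveniles differ in shape. `salmotherm` converts the three
stages' thermal performance into a common currency — the likelihood of
surviving to the next stage — at every river kilometre and day, then
weights those surfaces by where and when each life stage is actually
present. It is written for quantitative fisheries ecologists and
cold-water management analysts.

## Models

All three models are evaluated per pixel of a (river-km × day)
temperature grid `T`.

**Pre-spawn holding (adults).** Maintenance metabolism
`B_h = c₀·M^b·e^{D·T}` (mgO₂ d⁻¹ kg⁻¹; `c₀ = 1565.04`, `b = −0.217`,
`D = 0.068 °C⁻¹`, `M = 7.37 kg`), summed over the holding period and
converted to MJ kg⁻¹ (1 mgO₂ = 1.358442·10⁻⁵ MJ) to give the holding cost
`E_H`. A female succeeds when her energy ledger stays above the
post-spawn carcass floor:

```
E_I·(1 − g_f) − E_M − E_H ≥ E_D
```

with initial muscle energy density `E_I ~ N(11.7, 1.0)` MJ kg⁻¹ for
spring-run (`N(8.0, 1.0)` fall-run), migration cost `E_M` (2.5 / 2.0),
gonad fraction `g_f = 0.14` and `E_D = 3.4` MJ kg⁻¹. Spawn dates are
Monte-Carlo sampled (1000 draws per pixel) from the spawning phenology
truncated at the arrival day; arrivals after the phenology peak spawn
immediately.

**Embryo incubation.** Daily development accrues at
`0.001044·T + 0.00056` until it reaches 1 (emergence); cumulative
mortality is `M_T = 1 − exp(−s_T·Σ max(0, T_i − T_crit))` with
`s_T = 0.024 °C⁻¹ d⁻¹` and `T_crit = 12 °C`. Egg-to-fry survival is
`1 − M_T`.

**Juvenile growth to smolt.** Mass-standardized growth
`Ω = Food·d·(T + T_corr − T_L)·(1 − e^{g·(T + T_corr − T_U)})`
(% mass d⁻¹ per 1 g fish; `d = 0.415`, `g = 0.315`, `T_L = 1.833 °C`,
`T_U = 24.918 °C`, field correction `T_corr = 3 °C`, ration level
`Food = 0.65`). Daily mass follows `M_{t+1} = M_t + (Ω/100)·M_t^{1−α}`
(`α = 0.338`) from 0.46 g at emergence to the 6 g smolt threshold, while
survival decays as `S_{t+1} = S_t·e^{−μ}`, `μ = X_u·M_t^f`
(`X_u = 0.00753 d⁻¹`, `f = −0.27`). Smolting success is reported relative
to the constant-optimal-temperature trajectory.

Temperature grids are built from sparse monitor records: duplicates at a
(km, date) cell are averaged, temporal gaps shorter than 30 days are
linearly interpolated per monitor, and each date is linearly interpolated
in space between its observing monitors (no extrapolation — cells beyond
the outermost observing monitor stay masked). Phenology (Julian day) and
spatial (river-km) distributions are fitted as Gaussians by per-year
percentage-weighted moments and sampled to weight the surfaces.

## Worked example

Headline model predictions from the Python API:

```python
>>> import salmotherm as st
>>> st.optimal_growth_temperature()       # field temperature maximizing growth
16.018356249378975
>>> st.max_smolt_survival()               # (survival fraction, days to 6 g)
(0.5922696034982418, 83)
>>> st.embryo_survival_constant(13.0)     # (incubation days, egg-to-fry survival)
(71, 0.18195424947803895)
>>> st.max_holding_days(16.0, st.spring_run_budget())
101
```

Growth peaks at 16 °C; a fry emerging at that optimum smolts on day 83
with 59% of its cohort surviving size-dependent predation. At a constant
13 °C, eggs incubate 71 days and only ~18% emerge as fry, while any water
at or below 12 °C costs embryos nothing. A mean-energy spring-run female
can afford at most 101 days of holding at 16 °C.

End-to-end on a synthetic river (YAML configuration naming the river
scenario, populations and seed):

```sh
$ salmotherm run --config examples/fall_run.yaml --out out/
fall/spawning: weighted mean 51.0% vs unweighted 56.0% (mitigation -5.0 points)
fall/egg_to_fry: weighted mean 43.9% vs unweighted 17.7% (mitigation +26.2 points)
fall/smolting: weighted mean 85.4% vs unweighted 92.9% (mitigation -7.5 points)
```

Each line compares survival sampled where/when the population actually
occurs (weighted) against the whole river-year average (unweighted); the
mitigation index is their difference in percentage points — here the
fall-run's spawning locations strongly shelter its embryos (+26 points).
`salmotherm simulate`, `salmotherm grid` and `salmotherm compare` expose
the individual pipeline stages.

## Outputs

A run writes, deterministically for a given configuration:

- `temperature_grid.csv` — long format `km, date, temp_c, valid`;
  `temperature_matrix.csv` — dense km × date matrix, missing cells −999.
- `surface_<pop>_<stage>.csv` — long format
  `km, date, stage, population, likelihood_pct, valid`, plus a dense
  `*_matrix.csv` (masked cells −999, never 0).
- `weighted_<pop>_<stage>.csv` — the weighted sample vector
  (`likelihood_pct`), one row per retained draw.
- `summary.json` — per stage × population: mean, median, quartiles,
  5th/95th percentiles for weighted and unweighted results, pixel counts
  and the mitigation index; fitted distribution parameters.
- `resolved_config.yaml` — the fully resolved configuration of the run.

Synthetic input CSVs use headers `km, date, temp_c` (monitor records) and
`julian_day | river_km, count, year` (survey counts).

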