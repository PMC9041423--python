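# Methods

`salmotherm` scores the likelihood that a Chinook salmon survives each of
three freshwater life stages — pre-spawn holding, embryo incubation, and
stream rearing to smolt size — at every pixel of a 1 river-km × 1 day
temperature grid, then compares whole-river results against results
weighted by where and when each life stage actually occurs. This note
records the models, the conventions the equations leave open, the
numerical choices, and what the synthetic test scenarios do and do not
demonstrate.

## Coordinate and grid conventions

River kilometre 0 is the downstream confluence; km increases upstream to
an impassable dam at the highest km. The grid holds mean daily
temperature (°C) on integer km × calendar-day cells; invalid cells are
NaN. Dates are calendar dates internally and converted to Julian day
(1–366) only where phenology enters.

Grid construction from monitor records applies, in order:

1. **Duplicate averaging.** Monitor positions are rounded to the nearest
   integer km (ties rounded away from the confluence — an arbitrary,
   documented tie-break); multiple records at one (km, date) cell are
   arithmetically averaged.
2. **Temporal gap filling.** Per monitor, interior runs of missing days
   *strictly shorter* than 30 days are linearly interpolated between the
   flanking observations; runs of 30+ days and leading/trailing missing
   days stay missing. The strict inequality is deliberate: a 30-day gap
   is treated as unrecoverable.
3. **Spatial interpolation.** Per date, temperatures are linearly
   interpolated between the monitors observing that date. Cells upstream
   or downstream of every observing monitor are masked rather than
   extrapolated: extrapolating an exponential-sensitivity quantity like
   holding cost from two interior monitors is not defensible, and a
   masked pixel is an honest "no data".

## Life-stage models

### Adult holding energetics

Maintenance metabolism `B_h = c₀·M^b·e^{DT}` with `c₀ = 1565.04 mgO₂ d⁻¹
kg⁻¹`, mass exponent `b = −0.217`, temperature exponent `D = 0.068 °C⁻¹`,
adult female mass `M = 7.37 kg`; daily costs are summed over the holding
path and converted at 1 mgO₂ = 1.358442·10⁻⁵ MJ. A 1 °C rise multiplies
daily cost by e^0.068 ≈ 1.07, which is why holding duration, not any
single hot day, dominates adult outcomes.

**Spawning success** at pixel (km, arrival day): per Monte-Carlo draw, a
spawn date is sampled from the fitted spawning Gaussian truncated at the
arrival day, the holding cost `E_H` is accumulated at that km from
arrival to spawn date, and an initial energy density `E_I` is drawn; the
draw succeeds when

```
E_I·(1 − g_f) − E_M − E_H ≥ E_D .
```

Conventions fixed here, where the inequality's published framings are
ambiguous or self-contradictory:

- *Direction*: success means the remaining energy stays **at or above**
  the post-spawn floor `E_D = 3.4 MJ kg⁻¹`. This is the only direction
  consistent with a finite maximum holding duration (a mean-energy
  spring-run female affords 101 whole days at 16 °C, computed by the
  package).
- *Gonad cost* `g_f·E_I` is 14% of the **drawn** energy density, not of
  the population mean — the cost is defined as a proportion of the
  individual's starting reserves.
- *Peak spawning* (after which arrivals spawn immediately, at zero
  holding cost) is the mean of the fitted spawn Gaussian.
- Spawn-date and `E_I` draws are independent; each pixel uses a
  deterministic substream seeded by (run seed, km, date index), so
  results are reproducible without cross-pixel correlation.
- Holding happens at the fish's own pixel km (holding habitat equated
  with spawning habitat, the redd-survey convention); no movement.
- Pixels are masked outside the arrival window `[earliest observed
  arrival − 30 d, latest observed spawn + 30 d]` (falling back to
  mean ± 3 sd when a distribution is constructed without survey data),
  or when any draw's holding path crosses missing temperature or the
  grid edge.

### Embryo incubation

Daily development accrues at `0.001044·T + 0.00056` (clipped at zero for
sub-freezing nonsense inputs); emergence occurs on the first day the
cumulative sum reaches 1. At constant temperature this equals
`ceil(1/(0.001044·T + 0.00056))` — 71 days at 13 °C, 91 at 10 °C — and
the path implementation is tested against that closed form.

Mortality is `M_T = 1 − exp(−s_T·Σ max(0, T_i − 12.0))`,
`s_T = 0.024 °C⁻¹ d⁻¹`. The exceedance is clamped at zero so cold days
never offset warm-day mortality; water at or below 12 °C contributes
exactly nothing. At a constant 13 °C the model gives 18.2% egg-to-fry
survival over the 71-day incubation. A 365-day incubation cap guards
against pathological cold paths; hitting it masks the pixel.

### Juvenile growth and smolting

Growth follows the ration- and field-corrected thermal performance curve

```
Ω(T) = Food·d·(T + T_corr − T_L)·(1 − e^{g(T + T_corr − T_U)})
```

with `d = 0.415`, `g = 0.315`, `T_L = 1.833 °C`, `T_U = 24.918 °C`,
`T_corr = 3.0 °C` (laboratory-to-field shift) and `Food = 0.65` (field
ration as a fraction of ad libitum). Ω is returned as-is outside the
viable range — negative growth is mass loss, handled by the survival
layer, not clamped. The maximizing field temperature is found by bounded
scalar minimization (tolerance 10⁻⁴ °C) and equals 16.02 °C; it is
independent of `Food`.

Daily mass: `M_{t+1} = M_t + (Ω/100)·M_t^{1−α}`, `α = 0.338`, from
`M₁ = 0.46 g` on day 1 (emergence) to the 6 g smolt threshold. Daily
survival: `S_{t+1} = S_t·e^{−μ}` with `μ = X_u·M^f`, `X_u = 0.00753 d⁻¹`,
`f = −0.27`. Two conventions are deliberately pinned down:

- **Day counting**: the reported days-to-smolt is the 1-based day index
  on which mass first reaches 6 g; at the constant optimum this is day
  83 (82 growth updates).
- **Hazard mass**: μ is evaluated at the start-of-day mass (default,
  `survival_mass_convention="pre"`); a `"post"` option evaluates it at
  the post-growth mass. The choice matters at the third significant
  figure: terminal survival at the constant optimum is 59.2% (pre) vs
  59.5% (post); the continuous-time integral over the analytic mass
  trajectory gives 59.9%. The package documents and defaults to the
  pre-update convention.

Smolting success surfaces report survival relative to the
constant-optimal-temperature trajectory (so the optimum pixel scores
100%). Fry whose forward path ends, whose cohort loses all mass, or who
hit the 365-day rearing cap before 6 g are masked by default; a
`nonattainment="zero"` switch scores them 0% instead for management
scenarios where "didn't smolt here" should count against the pixel.

## Phenology and spatial weighting

Survey counts (Julian day or river-km, count, year) are converted to
within-year percentages so every surveyed year carries equal weight
regardless of run size, then fitted by weighted first and second moments.
Moment fitting is exact for Gaussian data binned to the 1-unit grid and
fully testable against the synthetic generator's ground truth; no
iterative likelihood machinery is warranted for unimodal count curves at
this resolution. Degenerate tables (a single support point) raise rather
than silently fitting sd = 0.

Weighting draws (Julian day, km) pairs independently from the fitted
timing and position Gaussians — the two are never fitted jointly — rounds
them to grid cells, drops draws landing off-grid or on masked pixels
(no resampling, keeping the literal contract that the number of draws
equals the grid's pixel count), and reads the surface at the survivors.
Multi-year grids replicate the phenology across years by assigning each
draw a uniformly random grid year. A run whose draws land on valid pixels
less than 1% of the time raises: the distributions do not belong to that
grid.

The **mitigation index** per stage is the weighted minus the unweighted
mean likelihood, in percentage points: positive when the population's
observed timing and positions avoid the thermally bad parts of the
river-year.

## Synthetic scenarios

The generator produces the full input suite with known ground truth:
temperature = annual mean + seasonal cosine (amplitude, peak day) +
linear warming with distance below the dam + i.i.d. daily noise; monitor
records are exact field samples with configurable outage gaps; survey
tables are rounded Gaussian draws tallied per year. A cosine year is a
deliberate simplification — it makes peak values and gradients closed-form
testable.

What it does **not** emulate: flow and discharge effects, thermal
stratification and refugia, diel cycles, autocorrelated weather,
non-Gaussian or multi-modal phenology, inter-annual phenology shifts, and
fish behaviour (movement, thermoregulation). Passing tests therefore
demonstrate that the pipeline's arithmetic, masking and sampling logic
are correct under the stated model, not that the model captures real
rivers' micro-thermal structure.

Default test scenarios use rivers of 10–30 km over one to two years —
sizes at which every stage's full Monte-Carlo surface computes in
seconds — with 200–1000 energy draws per pixel; the parameter-recovery
checks use 10⁴ survey observations, where the 2-standard-error band is
well inside the 1-unit acceptance window.

## Numerical choices and degenerate inputs

- Incubation/maturation uses a per-row cumulative sum and binary search
  (`searchsorted`), restricted to maximal contiguous valid runs so a gap
  in one season never contaminates paths entirely before or after it.
- Truncated-normal spawn dates are drawn by inverse-CDF transform
  (`ndtr`/`ndtri`); rounded spawn days are clipped to be no earlier than
  the arrival day. A truncation with essentially no mass above the
  arrival day is unreachable by construction (such arrivals are past the
  peak and spawn immediately).
- All randomness flows through explicit `numpy` `Generator` substreams
  derived from one run seed; there is no global random state, and a
  rerun of the same configuration is byte-identical on disk.
- Empty holding path costs exactly 0; zero-length or NaN-containing
  paths raise `InsufficientDataError` rather than guessing.
- Surface likelihoods are validated into [0, 100]; the smolting ratio is
  clipped against floating-point overshoot of the optimum.
- Dense matrix exports use −999 as the mask sentinel (never 0, which is
  a legitimate likelihood).

## Known limitations

- Migration cost `E_M` is a fixed per-run constant; it does not vary
  with distance, flow or temperature en route.
- Smolting is scored only for natal-ground rearing; fry/parr emigration
  strategies and outmigration survival are out of scope.
- The maximum-survival normalization makes smolting success a relative
  measure; absolute cohort survival is available from
  `max_smolt_survival` and `grow_to_smolt`.
- Spatial interpolation is linear along the channel; no network
  topology, tributaries or geostatistics.
- The Gaussian phenology family is a modelling choice; strongly skewed
  or bimodal run timing would need a different fit before weighting.
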