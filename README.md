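# brantsim

An individual-based model of black brant (*Branta bernicla nigricans*)
wintering on eelgrass (*Zostera marina*) in a shallow Mexican coastal
embayment, together with the experiment designs and observed-data statistics
used to ask: **which environmental driver limits the birds' ability to fatten
and migrate north in spring?**

It is aimed at quantitative ecologists who want a tested, scriptable
implementation of a tidal-forager energetics model — the kind used to predict
how eelgrass biomass and shoot length, sea level, and flock numbers translate
into survival, body-mass gain, and duration of stay of migratory geese.

## The model

Space is a bay of 91 patches of 500 × 500 m, each with a fixed shore
elevation (m relative to mean lower low water) and a stock of rooted eelgrass
(g dry mass m⁻²); a fixed fraction (0.05) of the rooted stock floats as
detached wrack. Time runs in 1-h steps from 1 August to 15 May, through
diurnal, lunar, and tidal cycles. Water depth over a patch is tidal height
minus elevation; rooted eelgrass is edible when the patch is exposed or the
canopy top is within neck reach (0.4 m) of the surface, floating eelgrass at
any tidal stage.

Birds are simulated as flocks of 100 identical individuals (super-
individuals) of three types — fall migrants, winter residents, spring
migrants — arriving on uniformly drawn dates within type-specific windows.
Each bird carries an energy store

> store = (body mass − lean mass) × fat energy density,

eats at a capped Holling type-II rate `min(q_max, aB / (1 + ahB))` of the
edible biomass density *B*, and assimilates `intake × energy content ×
digestibility` kJ h⁻¹ against a seasonal requirement. Every hour each flock
moves to the (patch, resource) pair that maximizes its assimilation rate, and
its consumption depletes the patch before the next flock chooses —
competition is purely exploitative. Stores are capped at a date-dependent
target; a store that falls to zero is death by starvation. Fall migrants
leave 11 days after arrival regardless of condition; winter residents and
spring migrants leave once a departure date **and** a departure store are
both reached.

On top of the simulator:

* **experiments** — *baseline* runs (all four drivers at year values, five
  replicates with 95% CIs), *single-variable* runs (one driver varied, the
  others held at cross-year means; importance = |prediction − all-mean
  prediction|), and a *migration threshold* sweep over January biomass;
* **observed_stats** — year-trend regressions with a residual-autocorrelation
  screen (±1.96/√n per lag), MA(1)-error refits when lag 1 is flagged, Holm
  step-down adjustment across the family, and Welch/Bartlett comparisons of
  body mass and survival between low- and high-biomass years;
* **synthetic_data** — generators for every input (bay, tides, year series,
  body-mass/survival surrogates) with the generating truth returned for
  recovery tests.

## Worked example

```python
import brantsim as bs

params = bs.EnergeticsParams()                     # documented defaults
for b in (30.0, 80.0):
    scn = bs.YearScenario(year=2005, jan_biomass=b, jan_shoot=0.35,
                          winter_population=15_000.0, sea_level_offset=0.0)
    s = bs.run_simulation(scn, params, seed=42).summary
    print(f"biomass {b:5.1f}: spring survival {s['survival_spring_migrant']:.2f}, "
          f"emigration {s['emigration_spring_migrant']:.2f}, "
          f"stay {s['stay_spring_migrant']:.1f} d, "
          f"spring mass gain {s['massgain_spring_migrant_spring']:.1f} g/day")
```

prints

```
biomass  30.0: spring survival 0.73, emigration 0.56, stay 38.4 d, spring mass gain 0.9 g/day
biomass  80.0: spring survival 1.00, emigration 1.00, stay 22.3 d, spring mass gain 25.3 g/day
```

At 30 g m⁻² of January eelgrass a quarter of the spring-migrant flocks
starve, only 56% manage to fatten to the departure store by 15 May, and the
survivors linger (long stay, near-zero mass gain); at 80 g m⁻² everyone
fattens quickly and departs soon after the spring departure date opens. The
same machinery drives `migration_threshold`, which sweeps a biomass grid and
reports the largest value at which spring migration is incomplete.

A command-line layer wraps the library:

```bash
brantsim synth years --seed 5 --out data/           # synthetic inputs
brantsim simulate --scenario data/scenarios.csv --year 1998 --seed 1 --out runs/
brantsim experiment single --var biomass --scenarios data/scenarios.csv --out runs/
brantsim threshold --scenarios data/scenarios.csv --out runs/
brantsim stats trends data/year_series.csv
```

## Layout

```
src/brantsim/
  environment.py     tides, light, patches, eelgrass dynamics
  foragers.py        flock energetics, functional response, patch choice
  engine.py          hourly scheduler, replicates
  experiments.py     baseline / single-variable designs, threshold sweep
  observed_stats.py  trend regressions, Holm, Welch/Bartlett
  synthetic_data.py  input generators with known ground truth
  io.py, cli.py      delimited-text / YAML interfaces, command line
docs/methods.md      model description, defaults, and their rationale
```
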