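# Methods

This note documents the model implemented in `brantsim`: its structure and
assumptions, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results.

## Model structure

**Space and time.** The bay is a set of patches (default 91 of 500 × 500 m,
area 250,000 m²) in three subsites, each patch with a fixed shore elevation
relative to mean lower low water (mllw). A season runs 1 August–15 May in
1-h steps (288 days, 6912 steps); dates are day indices with origin 1 August.
Seasons: fall 1 Aug–15 Dec, winter 16 Dec–15 Feb, spring 16 Feb–15 May.

**Tides and light.** Scenario tides default to an M2 + S2 + K1 harmonic sum
sampled hourly (mean level 0.8 m, amplitudes 0.58/0.23/0.33 m — a San-Diego-
like semidiurnal mixed tide), plus the scenario's sea-level anomaly added
uniformly to every step. Days have a fixed 06:00–18:00 daylight window; the
moon's illuminated fraction follows a 29.53-day cosine, and a night step is
"moonlit" when the fraction is ≥ 0.5 (configurable). Birds feed by day and on
moonlit nights with identical intake parameters; on dark nights they roost
(no intake) while the energy requirement still accrues. All of these are
deliberate simple substitutes for gauge data and astronomical ephemerides.

**Eelgrass.** Each patch holds rooted eelgrass (g dry m⁻²) and shoot length
(m), anchored to its January survey value: a piecewise-linear multiplicative
trajectory with nodes at 1 Aug / 15 Jan / 15 May (default ratios 1.6/1.0/1.3
for biomass, 1.4/1.0/1.2 for shoot length — summer peak, winter minimum,
spring regrowth, as in southern-range *Zostera* phenology) guarantees that on
15 January an ungrazed patch holds exactly the scenario's January value.
Grazing offtake accumulates separately and is subtracted from the seasonal
baseline, floored at zero, so consumption and growth compose without order
ambiguity. Floating (detached) eelgrass is a fixed fraction (0.05) of the
rooted stock, available at every tidal stage; consumption of either resource
depletes the single rooted pool (floating is treated as continuously
replenished detachment), which keeps the mass ledger single-pool and exact.

**Availability.** Water depth over a patch is tidal height − elevation.
Rooted eelgrass is edible when the patch is exposed (depth ≤ 0) or the canopy
top is within neck reach of the surface: depth − shoot length ≤ 0.4 m. The
0.4 m reach is the foraging-depth limit reported for the species; the
canopy-top rule is the simplest geometry using exactly the three quantities
known to control availability (tide, elevation, shoot length).

**Birds.** Flocks of 100 identical birds (super-individuals) of three types:
fall migrants, winter residents, spring migrants. Arrival dates are uniform
integer draws on type-specific windows (defaults: 1 Sep–15 Nov, 15 Oct–15
Dec, 16 Feb–31 Mar). The energy store is (body mass − lean mass) × fat
energy density; body mass is always derived from the store, so store–mass
consistency is exact by construction. Hourly intake follows a capped Holling
type-II functional response min(q_max, aB/(1 + ahB)); assimilation is intake
× energy content × digestibility. Stores are capped at a piecewise-linear
date-dependent target (fall/winter plateau, pre-migratory ramp to 15 Apr);
a store reaching zero kills the flock (starvation is the only mortality).
Fall migrants depart a fixed 11 days after arrival (the arrival day counts
as day 1 of the stay, so departure is checked on arrival-day + 11);
winter residents and spring migrants depart on the first day on or after
their departure day (1 Mar / 1 Apr) whose day-start store is at or above the
departure store.

**Scheduler.** Within each hour the fixed order is: tide/light state →
seasonal eelgrass update → (at the first step of each day) arrivals,
departure checks, daily records → availability → sequential patch/resource
choice with immediate depletion → energy update → starvation check. Flock
processing order is re-shuffled every step from the run's seed so no flock
holds a systematic depletion advantage; ties in patch choice break to the
lowest patch id, rooted before floating, and patches are sorted by id on
input so results do not depend on file row order. Day-scale rules are
evaluated at the first step of the day because departure quantities are
day-scale. Movement between patches carries no energetic cost. There is no
carry-over between years, no interference competition, and no food other
than eelgrass.

## Default parameters

All bird-side values are configurable (`EnergeticsParams`, `EelgrassParams`)
and are the package's documented defaults, chosen once for field realism for
a ~1.2–1.5 kg goose feeding on eelgrass:

| parameter | default | units | rationale |
|---|---|---|---|
| lean mass | 1100 | g | adult brant lean body mass |
| fat energy density | 34.3 | kJ g⁻¹ | energy density of fat tissue |
| arrival mass (fall/winter/spring) | 1300/1250/1200 | g | modest reserves on arrival |
| requirement (fall/winter/spring) | 40/45/50 | kJ h⁻¹ | ≈1.0–1.2 MJ day⁻¹ field expenditure |
| target store nodes | 7000 → 8500 → 13720 | kJ | plateau, then ramp to ≈400 g fat by 15 Apr |
| departure store | 12000 | kJ | ≈1450 g departure mass |
| departure day (winter/spring) | 1 Mar / 1 Apr | — | northward passage phenology |
| fall stay | 11 | days | mean stopover length of through-migrants |
| attack rate *a* | 0.8 | m² h⁻¹ | type-II initial slope |
| handling coefficient *h* | 0.025 | h g⁻¹ | asymptote 40 g h⁻¹ |
| max intake | 30 | g dry h⁻¹ | peck-rate ceiling |
| energy content | 16.0 | kJ g⁻¹ dry | eelgrass above-ground tissue |
| digestibility | 0.55 | — | proportion of energy assimilated |
| fall/spring through-populations | 10,000 each | birds | with a 10–30k winter population, ≈300 flocks |

With these defaults the bay supports full survival and prompt spring
departure at January biomasses above roughly 40 g m⁻², with starvation and
failed migration appearing below ≈30–35 g m⁻² — the response is in the
empirically relevant range without being tuned to any published prediction.

## Experiments

*Baseline*: every year's four drivers (January biomass, shoot length, winter
population, sea-level anomaly) at their year values; five replicates by
default (arrival dates are the only stochastic input); summaries are means
with normal-approximation 95% CIs. *Single-variable*: one driver at its year
value, the other three at unweighted cross-year means; one replicate; the
importance of a driver in a year is |predicted spring stay − all-mean
prediction|. The all-mean reference is computed once and shared across the
four designs, and every run in a design uses the same seed and bay, so a
year whose varied driver equals the mean reproduces the reference bitwise
and scores exactly zero. The stay metric averages over *all* spring flocks,
censoring dead flocks at death and non-departed flocks at 15 May, so it is
defined even in failure years.

*Threshold*: January biomass is swept over a grid with the other drivers at
their means under a common seed; the threshold is the largest grid value at
which fewer than 100% of spring-migrant flocks have departed by 15 May. The
sweep also reports the full emigration and stay curves and a duration-based
variant (largest biomass whose stay exceeds the top-of-grid stay by more
than half a day); grids lying entirely in one regime are flagged rather than
extrapolated.

## Observed-data statistics

Trends are ordinary least squares of value on year. Residuals are screened
lag by lag against the ±1.96/√n white-noise band (the specific per-lag test
being a documented choice); when lag 1 is flagged, the trend is refit as a
regression with MA(1) errors by maximum likelihood (ARIMA(0,0,1) with year
as exogenous regressor) and that fit is reported, with the OLS fit retained
alongside. Numerically exact fits (residual SS below 10⁻¹² of the total SS)
skip the screen, since their residuals are rounding noise. R² for the MA(1)
fit is 1 − SS_res/SS_tot of the regression line (a pseudo-R²). p-values are
Holm-adjusted across the family of regressions; constant (degenerate) series
are flagged and excluded from the family. Group comparisons split years at a
January-biomass threshold (60 g m⁻² by default) and apply Welch's
unequal-variance t-test and Bartlett's variance-homogeneity test within each
age–sex class; groups with fewer than two years are flagged, not tested.
Excluded years (e.g. an extreme ENSO outlier) are carried as a row flag and
dropped at fit time, never hard-coded.

## Synthetic data

The generators emulate the *structure* of the observed inputs: a ~91-patch
intertidal gradient (elevations spread over −0.7 to 0.5 m mllw with
lognormal, mean-preserving January biomass and shoot length), a semidiurnal
harmonic tide, and 30-year series with linear trends, optional MA(1) noise,
and ENSO anomaly years. The default year-series trends are the fitted
observed relationships for the system (e.g. biomass 9519 − 4.715 × year over
the 13 survey years), and the "1998-like" ENSO preset multiplies biomass by
0.25, raises sea level by 0.12 m, and sets the winter population to 70,000
birds. Body-mass and survival surrogates draw one annual mean per age–sex
class per year, with a configurable mean shift and variance inflation in
low-biomass years and a strong first-year (but weak adult) survival penalty.

They do **not** attempt to match the real tide gauge or survey datasets in
distribution; passing tests on synthetic data therefore demonstrate the
correctness and internal consistency of the machinery (recovery of known
trends, thresholds, and effects), not predictive accuracy for the real bay.
Year-specific published predictions (e.g. exact survival percentages in
particular years) depend on a parameter appendix that is not shipped;
reproducing them requires supplying those parameter values through the
config interfaces.

## Numerical choices and limitations

* Intake within an hour is capped by the patch's standing stock
  (`total ≤ B × area`), so depletion can never drive biomass negative.
* The energy ledger is exact: a flock's store change equals Σassimilated −
  Σrequirement except where truncated by the target cap (≤) or by death (≥);
  tests verify this at 10⁻⁶ relative tolerance on full-scale runs.
* The within-hour foraging loop is JIT-compiled (numba); a pure-python
  reference implementation of the patch-choice argmax is kept and tested
  equivalent, and all stochastic draws go through seeded numpy generators,
  so runs are exactly reproducible.
* Replicate seeds derive from the base seed via `SeedSequence.spawn`; CIs
  use the normal approximation (appropriate for 5 replicates of means over
  hundreds of flocks).
* Problem sizes used in the shipped tests — a 12-patch bay for unit tests,
  the full 91 × 300-flock season for the ledger check, 53 runs for the
  single-variable suite — were chosen so the whole suite exercises the model
  at production scale while remaining quick to run.
* Known limitations: no alternative foods (*Ruppia*, *Ulva*), no hunting or
  disturbance mortality, no interference competition, no within-flock
  heterogeneity, no between-year carry-over, idealized light/tide models,
  and a placeholder seasonal eelgrass trajectory. These mirror the scope of
  the modelled system; the first two mean that failure years in the model
  are conservative relative to real birds, which can partially compensate.
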