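"""Generators for every input the pipeline needs, with known ground truth.

These emulate the structure of the observed inputs — a bay of ~91 intertidal
patches across three subsites, a semidiurnal tide with a mean-sea-level
offset, and 30-year observation series with linear trends, ENSO-like anomaly
years and optional MA(1) noise — without attempting to statistically match
the real gauge or survey data.  Every generator is a pure function of
(config, rng): identical inputs give identical outputs, and the true
parameters are returned alongside the surrogate data for recovery tests.

The default year-series trends are the fitted observed relationships for the
system (e.g. January eelgrass biomass ~ 9519 - 4.715 x year over the 13
survey years), so the generated ensemble spans the same regimes: a long-term
biomass decline crossing the migration-threshold region, an extreme
1998-like ENSO year (biomass x 0.25, sea level + 0.12 m, ~70,000 birds),
and low/high-biomass groups of years for the body-mass and survival
surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import N_STEPS, SUBSITES, TideSeries

AGE_CLASSES = ("first_year", "adult")
SEXES = ("female", "male")


def _default_mass_base() -> dict:
    # g, annual mean body mass by age-sex class
    return {("first_year", "female"): 1150.0, ("first_year", "male"): 1250.0,
            ("adult", "female"): 1300.0, ("adult", "male"): 1450.0}


def _default_survival_base() -> dict:
    return {"first_year": 0.46, "adult": 0.85}


def _default_survival_low_effect() -> dict:
    # first-year survival drops sharply in low-biomass years; adults compensate
    return {"first_year": -0.20, "adult": -0.03}


def _default_scenario_years() -> tuple:
    return tuple(range(1997, 2007)) + (2011, 2012, 2013)


@dataclass
class SynthConfig:
    """Knobs of all synthetic generators (one config, one seed)."""

    seed: int = 0
    # bay
    n_patches: int = 91
    elevation_range: tuple[float, float] = (-0.7, 0.5)
    patch_area: float = 250_000.0
    jan_biomass_mean: float = 80.0      # g m^-2
    jan_biomass_cv: float = 0.35
    jan_shoot_mean: float = 0.35        # m
    jan_shoot_cv: float = 0.20
    # tide harmonics (M2, S2, K1)
    tide_mean_level: float = 0.8
    tide_amplitudes: tuple[float, float, float] = (0.58, 0.23, 0.33)
    tide_phases: tuple[float, float, float] = (0.0, 0.7, 1.4)
    # year series
    start_year: int = 1991
    n_years: int = 30
    scenario_years: tuple = field(default_factory=_default_scenario_years)
    biomass_trend: tuple[float, float] = (9519.0, -4.715)
    shoot_trend: tuple[float, float] = (25.24, -0.0125)
    sea_level_trend: tuple[float, float] = (-6.524, 0.0033)
    mexico_pop_trend: tuple[float, float] = (1_918_118.0, -909.7)
    bsq_pop_trend: tuple[float, float] = (-230_765.0, 125.0)
    biomass_sd: float = 10.0
    shoot_sd: float = 0.03
    sea_level_sd: float = 0.02
    sea_level_ma1: float = 0.5          # MA(1) coefficient of sea-level noise
    mexico_pop_sd: float = 15_000.0
    bsq_pop_sd: float = 5_000.0
    # ENSO preset ("enso1998-like"): biomass -75%, sea level +12 cm, influx
    enso_years: tuple = (1998,)
    enso_sea_level_rise: float = 0.12
    enso_biomass_mult: float = 0.25
    enso_population: float = 70_000.0
    # body-mass / survival surrogates
    biomass_threshold: float = 60.0
    mass_base: dict = field(default_factory=_default_mass_base)
    mass_low_effect: float = -30.0      # g, shift of low-biomass-year means
    mass_sd: float = 40.0               # g, between-year sd of annual means
    mass_low_sd_mult: float = 2.0       # variance inflation in low years
    survival_base: dict = field(default_factory=_default_survival_base)
    survival_low_effect: dict = field(default_factory=_default_survival_low_effect)
    survival_sd: float = 0.03

    def __post_init__(self) -> None:
        for v in (self.jan_biomass_cv, self.jan_shoot_cv, self.biomass_sd,
                  self.shoot_sd, self.sea_level_sd, self.mass_sd,
                  self.survival_sd):
            if v < 0:
                raise ValueError("standard deviations and CVs must be >= 0")


def _rng(config: SynthConfig, rng=None) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(config.seed if rng is None else rng)


def _lognormal(rng, mean: float, cv: float, n: int) -> np.ndarray:
    """Mean-preserving lognormal draws; degenerates to the mean at CV = 0."""
    if cv == 0 or mean == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def gen_bay(config: SynthConfig | None = None, rng=None) -> pd.DataFrame:
    """Patch map: elevations spanning the intertidal range across three
    subsites, January biomass and shoot length lognormal around their means."""
    config = config or SynthConfig()
    rng = _rng(config, rng)
    n = config.n_patches
    lo, hi = config.elevation_range
    elev = np.linspace(lo, hi, n)
    if n > 1:
        step = (hi - lo) / (n - 1)
        elev = elev + rng.uniform(-step / 4, step / 4, n)
    subsite = [SUBSITES[i * len(SUBSITES) // n] for i in range(n)]
    return pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "subsite": subsite,
        "elevation_m": elev,
        "area_m2": np.full(n, config.patch_area),
        "jan_biomass_g_m2": _lognormal(rng, config.jan_biomass_mean,
                                       config.jan_biomass_cv, n),
        "jan_shoot_m": _lognormal(rng, config.jan_shoot_mean,
                                  config.jan_shoot_cv, n),
    })


def gen_tide(config: SynthConfig | None = None, n_hours: int = N_STEPS,
             sea_level_offset: float = 0.0) -> TideSeries:
    """Hourly harmonic tide series (M2 + S2 + K1) plus a uniform offset."""
    config = config or SynthConfig()
    return TideSeries.from_harmonics(
        n_hours=n_hours, mean_level=config.tide_mean_level,
        amplitudes=config.tide_amplitudes, phases=config.tide_phases,
        sea_level_offset=sea_level_offset)


def _ma1_noise(rng, n: int, sd: float, theta: float) -> np.ndarray:
    e = rng.normal(0.0, sd, n + 1)
    return e[1:] + theta * e[:-1]


@dataclass
class SyntheticYears:
    """Surrogate observation tables plus the generating truth."""

    wide: pd.DataFrame          # one row per year, one column per variable
    long: pd.DataFrame          # year, variable, value, exclude_flag
    body_mass: pd.DataFrame     # year, age, sex, value (annual means, g)
    survival: pd.DataFrame      # year, age, sex, value (annual rates)
    scenarios: pd.DataFrame     # year-scenario driver table for the simulator
    truth: dict


def gen_year_series(config: SynthConfig | None = None, rng=None) -> SyntheticYears:
    """Observed-data surrogates: six trended series, ENSO anomalies, the
    1998 outlier, and per-year age-sex body-mass/survival samples."""
    config = config or SynthConfig()
    rng = _rng(config, rng)
    years = np.arange(config.start_year, config.start_year + config.n_years)
    if len(years) < 4:
        raise ValueError("need at least 4 years")
    enso = np.isin(years, config.enso_years)

    def line(trend):
        return trend[0] + trend[1] * years

    sea = line(config.sea_level_trend) + _ma1_noise(
        rng, len(years), config.sea_level_sd, config.sea_level_ma1)
    sea[enso] += config.enso_sea_level_rise
    mexico = np.maximum(line(config.mexico_pop_trend)
                        + rng.normal(0, config.mexico_pop_sd, len(years)), 1.0)
    bsq = np.maximum(line(config.bsq_pop_trend)
                     + rng.normal(0, config.bsq_pop_sd, len(years)), 1000.0)
    bsq[enso] = config.enso_population
    proportion = bsq / mexico

    in_scen = np.isin(years, config.scenario_years)
    biomass = np.full(len(years), np.nan)
    shoot = np.full(len(years), np.nan)
    biomass[in_scen] = np.maximum(
        line(config.biomass_trend)[in_scen]
        + rng.normal(0, config.biomass_sd, in_scen.sum()), 1.0)
    biomass[enso & in_scen] *= config.enso_biomass_mult
    shoot[in_scen] = np.maximum(
        line(config.shoot_trend)[in_scen]
        + rng.normal(0, config.shoot_sd, in_scen.sum()), 0.02)

    wide = pd.DataFrame({
        "year": years, "mexico_population": mexico, "bsq_population": bsq,
        "bsq_proportion": proportion, "sea_level": sea,
        "eelgrass_biomass": biomass, "eelgrass_shoot": shoot,
    })
    # the 1998-style outlier rows are flagged, not dropped
    exclude_vars = ("bsq_population", "bsq_proportion")
    long_rows = []
    for var in wide.columns[1:]:
        for y, v in zip(years, wide[var]):
            if np.isnan(v):
                continue
            long_rows.append({
                "year": y, "variable": var, "value": v,
                "exclude_flag": bool(var in exclude_vars and y in config.enso_years),
            })
    long = pd.DataFrame(long_rows)

    scen = wide.loc[in_scen, ["year"]].copy()
    scen["jan_biomass_g_m2"] = biomass[in_scen]
    scen["jan_shoot_m"] = shoot[in_scen]
    scen["winter_population"] = np.round(bsq[in_scen], -2)
    scen["sea_level_m"] = sea[in_scen] - sea[in_scen].mean()
    scen = scen.reset_index(drop=True)

    low = biomass < config.biomass_threshold
    mass_rows, surv_rows = [], []
    for i, y in enumerate(years):
        if not in_scen[i]:
            continue
        sd = config.mass_sd * (config.mass_low_sd_mult if low[i] else 1.0)
        for age in AGE_CLASSES:
            for sex in SEXES:
                m = config.mass_base[(age, sex)] \
                    + (config.mass_low_effect if low[i] else 0.0) \
                    + rng.normal(0, sd)
                mass_rows.append({"year": y, "age": age, "sex": sex, "value": m})
                s = config.survival_base[age] \
                    + (config.survival_low_effect[age] if low[i] else 0.0) \
                    + rng.normal(0, config.survival_sd)
                surv_rows.append({"year": y, "age": age, "sex": sex,
                                  "value": float(np.clip(s, 0.0, 1.0))})

    truth = {
        "trends": {"sea_level": config.sea_level_trend,
                   "mexico_population": config.mexico_pop_trend,
                   "bsq_population": config.bsq_pop_trend,
                   "eelgrass_biomass": config.biomass_trend,
                   "eelgrass_shoot": config.shoot_trend},
        "sea_level_ma1": config.sea_level_ma1,
        "low_biomass_years": years[in_scen & low].tolist(),
        "mass_low_effect": config.mass_low_effect,
        "mass_low_sd_mult": config.mass_low_sd_mult,
        "survival_low_effect": dict(config.survival_low_effect),
    }
    return SyntheticYears(wide=wide, long=long,
                          body_mass=pd.DataFrame(mass_rows),
                          survival=pd.DataFrame(surv_rows),
                          scenarios=scen, truth=truth)


def gen_scenarios(config: SynthConfig | None = None, rng=None) -> pd.DataFrame:
    """Year-scenario driver table (the 13-year surrogate ensemble)."""
    return gen_year_series(config, rng).scenarios
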