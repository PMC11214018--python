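"""Year-scenario experiment designs and the migration-biomass threshold.

Two designs mirror the study's simulation program.  *Baseline* runs give
every year its own observed drivers (January eelgrass biomass and shoot
length, winter population size, sea-level anomaly) with replicate arrival
stochasticity.  *Single-variable* runs vary one driver across years with the
other three held at their unweighted cross-year means; a driver's importance
in a year is the absolute difference between that year's predicted spring
duration of stay and the prediction with all four drivers at their means.

``migration_threshold`` sweeps January biomass over a grid (other drivers at
their means) and reports the largest biomass at which spring migrants fail
to all depart by 15 May, together with the full emigration-vs-biomass curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ReplicateResult, replicate_runs, run_simulation
from .environment import EelgrassParams
from .foragers import EnergeticsParams
from .synthetic_data import SynthConfig, gen_bay

DRIVERS = ("biomass", "shoot", "population", "sealevel")

# the metric of the single-variable design: mean length of stay of spring
# migrants across all flocks (departed flocks use their departure date, dead
# and still-present flocks are censored at death / season end)
METRIC = "stay_spring_migrant"


@dataclass
class YearScenario:
    """One year's four environmental drivers plus optional arrival windows."""

    year: int | str
    jan_biomass: float                  # g m^-2, bay-mean January biomass
    jan_shoot: float = 0.35             # m, bay-mean January shoot length
    winter_population: float = 15000.0  # birds (flocks of 100 on instantiation)
    sea_level_offset: float = 0.0       # m, anomaly added to every tide step
    arrival_windows: dict | None = None

    def __post_init__(self) -> None:
        if self.jan_biomass < 0 or self.winter_population < 0:
            raise ValueError("biomass and population must be >= 0")

    @classmethod
    def from_row(cls, row) -> "YearScenario":
        year = row["year"]
        try:
            # mixed-dtype rows upcast integer year labels to float
            year = int(year) if float(year).is_integer() else year
        except (TypeError, ValueError):
            pass
        return cls(year=year, jan_biomass=row["jan_biomass_g_m2"],
                   jan_shoot=row["jan_shoot_m"],
                   winter_population=row["winter_population"],
                   sea_level_offset=row.get("sea_level_m", 0.0))


def scenarios_from_frame(df: pd.DataFrame) -> list[YearScenario]:
    return [YearScenario.from_row(row) for _, row in df.iterrows()]


@dataclass
class ExperimentTable:
    """Tidy per-year experiment output, plus the shared all-mean reference."""

    design: str
    data: pd.DataFrame
    reference: dict | None = None
    replicate_tables: dict = field(default_factory=dict)


def _shared_bay(seed: int, bay: pd.DataFrame | None) -> pd.DataFrame:
    """One spatial pattern shared by every run of an experiment."""
    if bay is not None:
        return bay
    s = np.random.SeedSequence([seed, 9137]).generate_state(1)[0] % (2 ** 31)
    return gen_bay(SynthConfig(seed=int(s)))


def baseline_experiment(scenarios: list[YearScenario],
                        params: EnergeticsParams | None = None,
                        replicates: int = 5, seed: int = 0,
                        bay: pd.DataFrame | None = None,
                        eelgrass: EelgrassParams | None = None) -> ExperimentTable:
    """Replicate runs with all four drivers at their year-specific values.

    Emits per-year means and 95% CIs of every run summary (survival,
    emigration, duration of stay, seasonal mass-gain rates).
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    bay = _shared_bay(seed, bay)
    rows, reptables = [], {}
    for scn in scenarios:
        rep: ReplicateResult = replicate_runs(
            scn, params, n_replicates=replicates, base_seed=seed,
            bay=bay, eelgrass=eelgrass)
        reptables[scn.year] = rep
        for metric, r in rep.table.iterrows():
            rows.append({"year": scn.year, "metric": metric,
                         "mean": r["mean"], "sd": r["sd"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "n_replicates": int(r["n"])})
    return ExperimentTable(design="baseline", data=pd.DataFrame(rows),
                           replicate_tables=reptables)


def mean_scenario(scenarios: list[YearScenario]) -> YearScenario:
    """All four drivers at their unweighted arithmetic means across years."""
    return YearScenario(
        year="all_mean",
        jan_biomass=float(np.mean([s.jan_biomass for s in scenarios])),
        jan_shoot=float(np.mean([s.jan_shoot for s in scenarios])),
        winter_population=float(np.mean([s.winter_population for s in scenarios])),
        sea_level_offset=float(np.mean([s.sea_level_offset for s in scenarios])),
    )


def _vary_one(base: YearScenario, scn: YearScenario, which: str) -> YearScenario:
    fields = {"biomass": "jan_biomass", "shoot": "jan_shoot",
              "population": "winter_population", "sealevel": "sea_level_offset"}
    if which not in fields:
        raise ValueError(f"unknown driver {which!r}; expected one of {DRIVERS}")
    return replace(base, year=scn.year,
                   **{fields[which]: getattr(scn, fields[which])})


def single_variable_experiment(scenarios: list[YearScenario],
                               params: EnergeticsParams | None = None,
                               which: str = "biomass", seed: int = 0,
                               bay: pd.DataFrame | None = None,
                               eelgrass: EelgrassParams | None = None,
                               reference: dict | None = None) -> ExperimentTable:
    """One-at-a-time design: one driver at its year value, others at means.

    Single replicate per run (replicate consistency is established by the
    baseline design).  Every run, including the all-mean reference, uses the
    same seed and bay, so a year whose varied driver equals the cross-year
    mean reproduces the reference bitwise and scores an importance of
    exactly zero.  Pass ``reference`` (from a previous call) to reuse the
    all-mean run across the four drivers.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    bay = _shared_bay(seed, bay)
    base = mean_scenario(scenarios)
    if reference is None:
        ref = run_simulation(replace(base, year="all_mean"), params, seed=seed,
                             bay=bay, eelgrass=eelgrass)
        reference = dict(ref.summary)
    rows = []
    for scn in scenarios:
        varied = _vary_one(base, scn, which)
        res = run_simulation(varied, params, seed=seed, bay=bay,
                             eelgrass=eelgrass)
        rows.append({
            "year": scn.year, "driver": which,
            "driver_value": {"biomass": varied.jan_biomass,
                             "shoot": varied.jan_shoot,
                             "population": varied.winter_population,
                             "sealevel": varied.sea_level_offset}[which],
            "stay_spring": res.summary[METRIC],
            "survival_spring": res.summary["survival_spring_migrant"],
            "emigration_spring": res.summary["emigration_spring_migrant"],
            "importance": abs(res.summary[METRIC] - reference[METRIC]),
        })
    return ExperimentTable(design=f"vary_{which}", data=pd.DataFrame(rows),
                           reference=reference)


def single_variable_suite(scenarios: list[YearScenario],
                          params: EnergeticsParams | None = None, seed: int = 0,
                          bay: pd.DataFrame | None = None,
                          eelgrass: EelgrassParams | None = None) -> dict:
    """All four single-variable designs sharing one all-mean reference."""
    bay = _shared_bay(seed, bay)
    out: dict[str, ExperimentTable] = {}
    reference = None
    for which in DRIVERS:
        tab = single_variable_experiment(scenarios, params, which, seed=seed,
                                         bay=bay, eelgrass=eelgrass,
                                         reference=reference)
        reference = tab.reference
        out[which] = tab
    return out


@dataclass
class ThresholdResult:
    """Migration threshold over January biomass, with the full curve."""

    threshold: float | None             # g m^-2, largest failing grid value
    threshold_stay: float | None        # duration-based variant
    curve: pd.DataFrame                 # biomass, emigration, stay, survival
    flag: str                           # "ok" | "all_succeed" | "all_fail"


def migration_threshold(params: EnergeticsParams | None = None,
                        biomass_grid=np.arange(10.0, 101.0, 10.0),
                        seed: int = 0, *,
                        scenarios: list[YearScenario] | None = None,
                        base_scenario: YearScenario | None = None,
                        bay: pd.DataFrame | None = None,
                        eelgrass: EelgrassParams | None = None) -> ThresholdResult:
    """Largest January biomass at which spring migration is incomplete.

    Runs the grid under common seeds with the non-biomass drivers at their
    cross-year means (or those of ``base_scenario``).  Failure = less than
    100% of spring-migrant flocks departed by 15 May.  A grid lying entirely
    in one regime is flagged and yields no threshold.
    """
    grid = np.sort(np.asarray(biomass_grid, dtype=float))
    if grid.size < 2:
        raise ValueError("biomass grid needs at least two points")
    if base_scenario is None:
        base_scenario = (mean_scenario(scenarios) if scenarios
                         else YearScenario(year="threshold", jan_biomass=grid[0]))
    bay = _shared_bay(seed, bay)
    rows = []
    for b in grid:
        scn = replace(base_scenario, year=f"b{b:g}", jan_biomass=float(b))
        res = run_simulation(scn, params, seed=seed, bay=bay, eelgrass=eelgrass)
        rows.append({"biomass": b,
                     "emigration_spring": res.summary["emigration_spring_migrant"],
                     "stay_spring": res.summary[METRIC],
                     "survival_spring": res.summary["survival_spring_migrant"]})
    curve = pd.DataFrame(rows)
    failing = curve["emigration_spring"] < 1.0
    if failing.all():
        return ThresholdResult(None, None, curve, "all_fail")
    if not failing.any():
        return ThresholdResult(None, None, curve, "all_succeed")
    threshold = float(curve.loc[failing, "biomass"].max())
    # duration-based variant: stay still elevated above the high-biomass stay
    stay_ok = curve["stay_spring"].iloc[-1]
    long_stay = curve["stay_spring"] > stay_ok + 0.5
    threshold_stay = (float(curve.loc[long_stay, "biomass"].max())
                      if long_stay.any() else None)
    return ThresholdResult(threshold, threshold_stay, curve, "ok")
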