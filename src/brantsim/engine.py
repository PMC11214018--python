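"""Hourly scheduler: arrivals, foraging, energy accounting, departures.

A simulation covers one non-breeding season, 1 August (day 0) to 15 May
(day 287), in 1-h steps.  The fixed within-step order is:

    tide/light state -> seasonal eelgrass update (daily) -> arrivals and
    departure checks (first step of the day) -> availability -> sequential
    patch/resource choice with depletion (flock order re-shuffled every
    step) -> energy and body-mass update -> starvation check.

Day-scale rules (arrivals, departures, seasonal growth) are evaluated at the
first step of each day.  Fall migrants leave ``fall_stay_days`` days after
arrival regardless of condition; winter residents and spring migrants leave
on the first day on or after their departure day on which their store has
reached the departure store.  A store that falls to zero is death by
starvation; starvation is the only mortality source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernel import assign_and_feed
from .environment import (N_DAYS, N_STEPS, EelgrassParams, LightCalendar,
                          TideSeries)
from .foragers import (FLOCK_TYPES, EnergeticsParams, feeding_permitted)

PENDING, PRESENT, DEPARTED, DEAD = 0, 1, 2, 3
_STATUS_NAMES = {PENDING: "pending", PRESENT: "present",
                 DEPARTED: "departed", DEAD: "dead"}

SEASONS = ("fall", "winter", "spring")


@dataclass(frozen=True)
class SeasonCalendar:
    """Season bounds (inclusive day indices, origin 1 Aug).

    Defaults: fall 1 Aug-15 Dec, winter 16 Dec-15 Feb, spring 16 Feb-15 May;
    the three seasons partition the simulated window.
    """

    fall: tuple[int, int] = (0, 136)
    winter: tuple[int, int] = (137, 198)
    spring: tuple[int, int] = (199, 287)

    def __post_init__(self) -> None:
        if not (self.fall[0] == 0 and self.fall[1] + 1 == self.winter[0]
                and self.winter[1] + 1 == self.spring[0]
                and self.spring[1] == N_DAYS - 1):
            raise ValueError("seasons must partition the 1 Aug-15 May window")

    def season_of(self, day: int) -> str:
        if day <= self.fall[1]:
            return "fall"
        if day <= self.winter[1]:
            return "winter"
        return "spring"

    def season_codes(self) -> np.ndarray:
        """Per-day season index (0 fall, 1 winter, 2 spring)."""
        codes = np.zeros(N_DAYS, dtype=np.int64)
        codes[self.winter[0]:self.winter[1] + 1] = 1
        codes[self.spring[0]:] = 2
        return codes


DEFAULT_CALENDAR = SeasonCalendar()


@dataclass
class SimulationResult:
    """Per-flock fates and season summaries of one run."""

    flocks: pd.DataFrame
    summary: dict
    patch_biomass: pd.DataFrame
    mass_daily: np.ndarray            # (n_flocks, n_days), NaN when absent
    seed: int
    energy: dict | None = None        # hourly assimilation/requirement traces


def schedule_arrivals(counts: dict, windows: dict, rng) -> dict:
    """Draw each flock's arrival day uniformly on its type's window.

    ``counts`` maps flock type -> number of flocks; ``windows`` maps type ->
    (first, last) inclusive day indices.  Deterministic for a fixed rng seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for ftype in FLOCK_TYPES:
        first, last = windows[ftype]
        if first > last:
            raise ValueError(f"arrival window inverted for {ftype}")
        if not (0 <= first and last < N_DAYS):
            raise ValueError(f"arrival window outside simulation span for {ftype}")
        out[ftype] = rng.integers(first, last + 1, size=counts.get(ftype, 0))
    return out


def _build_flocks(scenario, params: EnergeticsParams, rng) -> dict:
    counts = {
        "fall_migrant": int(round(params.fall_population / params.flock_size)),
        "winter_resident": int(round(scenario.winter_population / params.flock_size)),
        "spring_migrant": int(round(params.spring_population / params.flock_size)),
    }
    windows = dict(params.arrival_windows)
    override = getattr(scenario, "arrival_windows", None)
    if override:
        windows.update(override)
    arrivals = schedule_arrivals(counts, windows, rng)
    types, days = [], []
    for code, ftype in enumerate(FLOCK_TYPES):
        types.extend([code] * counts[ftype])
        days.extend(arrivals[ftype].tolist())
    type_code = np.array(types, dtype=np.int64)
    arrival_day = np.array(days, dtype=np.int64)
    mass0 = np.array([params.arrival_mass_by_type[FLOCK_TYPES[c]] for c in type_code])
    store0 = (mass0 - params.lean_mass) * params.fat_energy_density
    return {"type_code": type_code, "arrival_day": arrival_day,
            "store0": store0, "counts": counts}


def run_simulation(scenario, params: EnergeticsParams | None = None,
                   seed: int = 0, *, bay: pd.DataFrame | None = None,
                   eelgrass: EelgrassParams | None = None,
                   tide: TideSeries | None = None,
                   light: LightCalendar | None = None,
                   calendar: SeasonCalendar = DEFAULT_CALENDAR,
                   record_energy: bool = False) -> SimulationResult:
    """Run one season of the individual-based model.

    ``scenario`` supplies the year's four drivers (January eelgrass biomass
    and shoot length, winter population, sea-level anomaly).  ``bay`` is a
    patch map (columns id, subsite, elevation_m, area_m2, jan_biomass_g_m2,
    jan_shoot_m); it provides the spatial pattern, rescaled so its mean
    January biomass and shoot length equal the scenario's values.  When no
    bay or tide is supplied, synthetic defaults are generated from ``seed``.
    """
    params = params if params is not None else EnergeticsParams()
    eelgrass = eelgrass if eelgrass is not None else EelgrassParams()
    ss = np.random.SeedSequence(seed)
    s_bay, s_arrival, s_order = ss.spawn(3)

    if bay is None:
        from .synthetic_data import SynthConfig, gen_bay
        bay = gen_bay(SynthConfig(), rng=np.random.default_rng(s_bay))
    bay = bay.sort_values("id", kind="stable").reset_index(drop=True)

    jan_b = bay["jan_biomass_g_m2"].to_numpy(dtype=float).copy()
    jan_s = bay["jan_shoot_m"].to_numpy(dtype=float).copy()
    if jan_b.mean() > 0:
        jan_b *= scenario.jan_biomass / jan_b.mean()
    if jan_s.mean() > 0:
        jan_s *= scenario.jan_shoot / jan_s.mean()
    elev = bay["elevation_m"].to_numpy(dtype=float)
    area = bay["area_m2"].to_numpy(dtype=float)
    n_patches = len(bay)

    if tide is None:
        tide = TideSeries.from_harmonics(N_STEPS)
    tide_h = tide.adjusted + getattr(scenario, "sea_level_offset", 0.0)
    if len(tide_h) < N_STEPS:
        raise ValueError("tide series shorter than the simulation window")
    light = light if light is not None else LightCalendar.build()

    fl = _build_flocks(scenario, params, np.random.default_rng(s_arrival))
    type_code, arrival_day = fl["type_code"], fl["arrival_day"]
    n_flocks = len(type_code)
    n_birds = np.full(n_flocks, float(params.flock_size))
    store = fl["store0"].copy()
    store0 = fl["store0"].copy()

    # per-day precomputation
    days = np.arange(N_DAYS)
    bio_factor = np.asarray(eelgrass.biomass_factor(days), dtype=float)
    shoot_factor = np.asarray(eelgrass.shoot_factor(days), dtype=float)
    season_code = calendar.season_codes()
    req_by_code = np.array([params.requirement_by_season[s] for s in SEASONS])
    req_day = req_by_code[season_code]
    target_day = np.asarray(params.target_store(days), dtype=float)
    dep_day_by_code = np.array([-1, params.departure_day_winter,
                                params.departure_day_spring])

    status = np.zeros(n_flocks, dtype=np.int64)
    departure_day = np.full(n_flocks, -1, dtype=np.int64)
    death_day = np.full(n_flocks, -1, dtype=np.int64)
    cum_depl = np.zeros(n_patches)
    rooted_b = np.maximum(0.0, bio_factor[0] * jan_b - cum_depl)
    shoot = shoot_factor[0] * jan_s

    mass_daily = np.full((n_flocks, N_DAYS), np.nan)
    patch_biomass = np.zeros((N_DAYS, n_patches))
    tot_assim = np.zeros(n_flocks)
    tot_req = np.zeros(n_flocks)
    capped = np.zeros(n_flocks, dtype=bool)
    if record_energy:
        assim_trace = np.zeros((N_STEPS, n_flocks))
        req_trace = np.zeros((N_STEPS, n_flocks))

    chosen_patch = np.full(n_flocks, -1, dtype=np.int64)
    chosen_res = np.zeros(n_flocks, dtype=np.int64)
    intake = np.zeros(n_flocks)
    rng_order = np.random.default_rng(s_order)
    e_times_q = eelgrass.energy_content * eelgrass.digestibility
    ff = eelgrass.floating_fraction

    for t in range(N_STEPS):
        d, h = divmod(t, 24)
        if h == 0:
            rooted_b = np.maximum(0.0, bio_factor[d] * jan_b - cum_depl)
            shoot = shoot_factor[d] * jan_s
            status[(status == PENDING) & (arrival_day == d)] = PRESENT
            present = status == PRESENT
            # fall migrants: fixed-length stay (arrival day counts as day 1)
            leave = present & (type_code == 0) & (d - arrival_day >= params.fall_stay_days)
            # winter residents / spring migrants: date and store thresholds
            ws = present & (type_code > 0)
            leave |= ws & (d >= dep_day_by_code[type_code]) & (store >= params.departure_store)
            status[leave] = DEPARTED
            departure_day[leave] = d
            present = status == PRESENT
            patch_biomass[d] = rooted_b
            mass_daily[present, d] = params.mass_from_store(store[present])
            if not np.isfinite(store[present]).all():
                raise RuntimeError(f"non-finite energy store on day {d}")

        present_idx = np.flatnonzero(status == PRESENT)
        if present_idx.size == 0:
            continue
        depth = tide_h[t] - elev
        avail = (depth <= 0.0) | (depth - shoot <= params.max_reach)
        intake[:] = 0.0
        if feeding_permitted(bool(light.is_day[t]), bool(light.moonlit_night[t]), params):
            order = rng_order.permutation(present_idx)
            assign_and_feed(order, rooted_b, avail, area, n_birds,
                            params.attack_rate, params.handling_time,
                            params.max_intake, ff, cum_depl,
                            chosen_patch, chosen_res, intake)
        assim = intake[present_idx] * e_times_q
        req = req_day[d]
        raw = store[present_idx] + assim - req
        over = raw - target_day[d]
        capped[present_idx[over > 0]] = True
        new_store = np.minimum(raw, target_day[d])
        dead = raw <= 0.0
        new_store[dead] = 0.0
        store[present_idx] = new_store
        status[present_idx[dead]] = DEAD
        death_day[present_idx[dead]] = d
        tot_assim[present_idx] += assim
        tot_req[present_idx] += req
        if record_energy:
            assim_trace[t, present_idx] = assim
            req_trace[t, present_idx] = req

    result_flocks = _assemble_flocks(type_code, arrival_day, departure_day,
                                     death_day, status, store, mass_daily,
                                     calendar)
    summary = _summarize(result_flocks)
    energy = None
    if record_energy:
        energy = {"assimilated": assim_trace, "requirement": req_trace,
                  "store_initial": store0, "store_final": store.copy(),
                  "capped": capped}
    pb = pd.DataFrame(patch_biomass, columns=bay["id"].tolist())
    pb.index.name = "day"
    return SimulationResult(flocks=result_flocks, summary=summary,
                            patch_biomass=pb, mass_daily=mass_daily,
                            seed=seed, energy=energy)


def _season_gain(mass_row: np.ndarray, lo: int, hi: int) -> float:
    days = np.flatnonzero(~np.isnan(mass_row[lo:hi + 1])) + lo
    if days.size < 2:
        return np.nan
    return (mass_row[days[-1]] - mass_row[days[0]]) / (days[-1] - days[0])


def _assemble_flocks(type_code, arrival_day, departure_day, death_day,
                     status, store, mass_daily, calendar) -> pd.DataFrame:
    n = len(type_code)
    fate = [_STATUS_NAMES[s] for s in status]
    duration = np.empty(n)
    for i in range(n):
        if status[i] == DEPARTED:
            duration[i] = departure_day[i] - arrival_day[i]
        elif status[i] == DEAD:
            duration[i] = death_day[i] - arrival_day[i]
        elif status[i] == PRESENT:
            duration[i] = N_DAYS - arrival_day[i]
        else:                               # never arrived (window edge)
            duration[i] = 0.0
    rows = {
        "flock_id": np.arange(n),
        "type": [FLOCK_TYPES[c] for c in type_code],
        "arrival_day": arrival_day,
        "departure_day": departure_day,
        "death_day": death_day,
        "fate": fate,
        "duration_days": duration,
        "final_store_kj": store,
    }
    bounds = {"fall": calendar.fall, "winter": calendar.winter,
              "spring": calendar.spring}
    for season, (lo, hi) in bounds.items():
        rows[f"massgain_{season}"] = [
            _season_gain(mass_daily[i], lo, hi) for i in range(n)]
    return pd.DataFrame(rows)


def _summarize(flocks: pd.DataFrame) -> dict:
    """Flat per-type summary of one run (proportions in [0, 1], days, g/day)."""
    out = {}
    for ftype in FLOCK_TYPES:
        sub = flocks[flocks["type"] == ftype]
        n = len(sub)
        if n == 0:
            continue
        dead = (sub["fate"] == "dead").sum()
        departed = sub["fate"] == "departed"
        out[f"survival_{ftype}"] = 1.0 - dead / n
        out[f"emigration_{ftype}"] = departed.sum() / n
        out[f"duration_{ftype}"] = (
            sub.loc[departed, "duration_days"].mean() if departed.any() else np.nan)
        out[f"stay_{ftype}"] = sub["duration_days"].mean()
        for season in SEASONS:
            col = sub[f"massgain_{season}"]
            out[f"massgain_{ftype}_{season}"] = (
                col.mean() if col.notna().any() else np.nan)
    return out


@dataclass
class ReplicateResult:
    """Replicate-wise summaries with normal-approximation 95% CIs."""

    replicates: pd.DataFrame          # one row per replicate
    table: pd.DataFrame               # index metric; mean, sd, ci_low, ci_high
    seeds: list = field(default_factory=list)


def replicate_runs(scenario, params: EnergeticsParams | None = None,
                   n_replicates: int = 5, base_seed: int = 0,
                   **run_kwargs) -> ReplicateResult:
    """Run replicate simulations (stochastic arrival dates) and summarize.

    Replicate seeds derive deterministically from ``base_seed``; the CI is
    mean +/- 1.96 * sd / sqrt(n) and collapses to a point for n = 1.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(base_seed).spawn(n_replicates)]
    rows = []
    for s in seeds:
        res = run_simulation(scenario, params, seed=s, **run_kwargs)
        rows.append(res.summary)
    reps = pd.DataFrame(rows)
    mean = reps.mean()
    sd = (reps.std(ddof=1).fillna(0.0) if len(reps) > 1
          else pd.Series(0.0, index=mean.index))
    half = 1.96 * sd / np.sqrt(len(reps))
    table = pd.DataFrame({"mean": mean, "sd": sd,
                          "ci_low": mean - half, "ci_high": mean + half,
                          "n": len(reps)})
    return ReplicateResult(replicates=reps, table=table, seeds=seeds)
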