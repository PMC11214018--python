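import numpy as np
import pandas as pd
import pytest

from brantsim import (EnergeticsParams, YearScenario, replicate_runs,
                      run_simulation, schedule_arrivals)
from brantsim._kernel import assign_and_feed
from brantsim.engine import SeasonCalendar
from brantsim.environment import N_DAYS
from brantsim.foragers import best_patch_resource

from conftest import make_scenario


class TestScheduleArrivals:
    WINDOWS = {"fall_migrant": (31, 106), "winter_resident": (75, 136),
               "spring_migrant": (199, 242)}

    def test_degenerate_window(self):
        win = dict(self.WINDOWS, fall_migrant=(40, 40))
        out = schedule_arrivals({"fall_migrant": 50}, win, 0)
        assert (out["fall_migrant"] == 40).all()

    def test_uniform_mean(self):
        win = dict(self.WINDOWS, fall_migrant=(0, 30))
        draws = schedule_arrivals({"fall_migrant": 10_000}, win, 1)["fall_migrant"]
        se = np.sqrt((31 ** 2 - 1) / 12 / 10_000)
        assert abs(draws.mean() - 15.0) < 3 * se
        assert draws.min() >= 0 and draws.max() <= 30

    def test_same_seed_identical(self):
        counts = {"fall_migrant": 20, "winter_resident": 30, "spring_migrant": 10}
        a = schedule_arrivals(counts, self.WINDOWS, 7)
        b = schedule_arrivals(counts, self.WINDOWS, 7)
        for k in a:
            assert (a[k] == b[k]).all()

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            schedule_arrivals({"fall_migrant": 1},
                              dict(self.WINDOWS, fall_migrant=(50, 40)), 0)


class TestRunSimulation:
    def test_fall_migrants_stay_eleven_days(self, rich_scenario, small_params,
                                            small_bay):
        res = run_simulation(rich_scenario, small_params, seed=3, bay=small_bay)
        fall = res.flocks[res.flocks["type"] == "fall_migrant"]
        surviving = fall[fall["fate"] == "departed"]
        assert len(surviving) == len(fall)
        assert (surviving["duration_days"] == small_params.fall_stay_days).all()

    def test_superabundant_food_everyone_survives(self, rich_scenario,
                                                  small_params, small_bay):
        res = run_simulation(rich_scenario, small_params, seed=3, bay=small_bay)
        assert (res.flocks["fate"] != "dead").all()
        spring = res.flocks[res.flocks["type"] == "spring_migrant"]
        assert (spring["fate"] == "departed").all()
        # spring departure at the earliest day satisfying both rules
        assert (spring["departure_day"]
                >= np.maximum(spring["arrival_day"],
                              small_params.departure_day_spring)).all()

    def test_zero_food_starvation_at_closed_form_time(self, small_params,
                                                      small_bay):
        """With no eelgrass anywhere, death follows the analytic countdown
        through the season-dependent hourly requirement."""
        scn = make_scenario(jan_biomass=0.0, winter_population=500.0)
        res = run_simulation(scn, small_params, seed=5, bay=small_bay)
        assert (res.flocks["fate"] == "dead").all()
        cal = SeasonCalendar()
        req = small_params.requirement_by_season
        store0 = {t: small_params.store_from_mass(m)
                  for t, m in small_params.arrival_mass_by_type.items()}
        for _, f in res.flocks.iterrows():
            store, day = store0[f["type"]], f["arrival_day"]
            hours = 0
            while store > 0:
                store -= req[cal.season_of(min(day + hours // 24, N_DAYS - 1))]
                hours += 1
            assert f["death_day"] == f["arrival_day"] + (hours - 1) // 24

    def test_energy_ledger_balances(self, small_params, small_bay):
        scn = make_scenario(jan_biomass=35.0, winter_population=1000.0)
        res = run_simulation(scn, small_params, seed=9, bay=small_bay,
                             record_energy=True)
        e = res.energy
        delta = e["store_final"] - e["store_initial"]
        net = e["assimilated"].sum(axis=0) - e["requirement"].sum(axis=0)
        dead = (res.flocks["fate"] == "dead").to_numpy()
        free = ~e["capped"] & ~dead
        scale = np.maximum(np.abs(e["store_initial"]), 1.0)
        assert np.all(np.abs(delta - net)[free] <= 1e-6 * scale[free])
        # target cap only removes energy; starvation truncation only adds it
        cap_only = e["capped"] & ~dead
        assert np.all(delta[cap_only] <= net[cap_only] + 1e-6 * scale[cap_only])
        dead_only = dead & ~e["capped"]
        assert np.all(delta[dead_only] >= net[dead_only] - 1e-6 * scale[dead_only])

    def test_same_seed_reproducible(self, small_params, small_bay):
        scn = make_scenario(jan_biomass=40.0)
        a = run_simulation(scn, small_params, seed=21, bay=small_bay)
        b = run_simulation(scn, small_params, seed=21, bay=small_bay)
        pd.testing.assert_frame_equal(a.flocks, b.flocks)
        assert a.summary == pytest.approx(b.summary, nan_ok=True)

    def test_patch_order_invariance(self, small_params, small_bay):
        scn = make_scenario(jan_biomass=40.0)
        shuffled = small_bay.sample(frac=1.0, random_state=4)
        a = run_simulation(scn, small_params, seed=2, bay=small_bay)
        b = run_simulation(scn, small_params, seed=2, bay=shuffled)
        pd.testing.assert_frame_equal(a.flocks, b.flocks)

    def test_emigration_monotone_in_biomass(self, small_params, small_bay):
        emig = []
        for b in (15.0, 30.0, 60.0):
            res = run_simulation(make_scenario(jan_biomass=b), small_params,
                                 seed=13, bay=small_bay)
            emig.append(res.summary["emigration_spring_migrant"])
        assert emig == sorted(emig)

    def test_short_tide_series_rejected(self, small_params, small_bay):
        from brantsim import TideSeries
        with pytest.raises(ValueError):
            run_simulation(make_scenario(), small_params, seed=0,
                           bay=small_bay,
                           tide=TideSeries(heights=np.zeros(100)))


def test_kernel_matches_python_reference():
    """The JIT foraging loop and the pure-python argmax agree state by state."""
    from brantsim import EnergeticsParams
    params = EnergeticsParams()
    rng = np.random.default_rng(33)
    for _ in range(200):
        n = rng.integers(1, 15)
        rooted = rng.uniform(0, 100, n) * rng.integers(0, 2, n)
        avail = rng.integers(0, 2, n).astype(bool)
        expected = best_patch_resource(rooted, 0.05 * rooted, avail, params)
        chosen_patch = np.full(1, -9, dtype=np.int64)
        chosen_res = np.zeros(1, dtype=np.int64)
        intake = np.zeros(1)
        assign_and_feed(np.zeros(1, dtype=np.int64), rooted.copy(), avail,
                        np.full(n, 250_000.0), np.array([100.0]),
                        params.attack_rate, params.handling_time,
                        params.max_intake, 0.05, np.zeros(n),
                        chosen_patch, chosen_res, intake)
        got = None if chosen_patch[0] < 0 else (chosen_patch[0], chosen_res[0])
        assert got == expected


class TestReplicates:
    def test_single_replicate_point_ci(self, small_params, small_bay):
        rep = replicate_runs(make_scenario(), small_params, n_replicates=1,
                             base_seed=0, bay=small_bay)
        same = (rep.table["ci_high"] == rep.table["ci_low"]) \
            | (rep.table["ci_high"].isna() & rep.table["ci_low"].isna())
        assert same.all()

    def test_ci_matches_direct_recomputation(self, small_params, small_bay):
        rep = replicate_runs(make_scenario(jan_biomass=35.0), small_params,
                             n_replicates=4, base_seed=8, bay=small_bay)
        col = "stay_spring_migrant"
        vals = rep.replicates[col].to_numpy()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
        assert rep.table.loc[col, "ci_low"] == pytest.approx(vals.mean() - half)
        assert rep.table.loc[col, "ci_high"] == pytest.approx(vals.mean() + half)

    def test_replicates_need_at_least_one(self, small_params):
        with pytest.raises(ValueError):
            replicate_runs(make_scenario(), small_params, n_replicates=0)
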