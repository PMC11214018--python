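import numpy as np
import pandas as pd
import pytest
import scipy.stats

from brantsim import (compare_by_biomass, fit_trend, holm_adjust, trend_suite)
from brantsim.observed_stats import comparisons_to_frame


class TestFitTrend:
    def test_exact_line(self):
        year = np.arange(1990, 2010)
        fit = fit_trend(year, 2.0 * year - 100.0)
        assert fit.slope == pytest.approx(2.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.error_model == "iid"

    def test_constant_series_flagged(self):
        fit = fit_trend(np.arange(10), np.full(10, 3.0))
        assert fit.degenerate
        assert np.isnan(fit.p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(np.arange(3), np.arange(3.0))

    def test_exclude_flag_drops_rows(self):
        year = np.arange(1990, 2000, dtype=float)
        value = 1.5 * year
        value[3] = 1e6   # outlier year, flagged out
        excl = np.zeros(10, bool)
        excl[3] = True
        fit = fit_trend(year, value, exclude=excl)
        assert fit.n == 9
        assert fit.slope == pytest.approx(1.5, rel=1e-9)

    def test_lag1_flag_rate_near_nominal_for_white_noise(self):
        """Size of the lag-1 screen on iid residuals ~ alpha = 0.05."""
        rng = np.random.default_rng(2024)
        n, reps = 100, 400
        year = np.arange(n, dtype=float)
        hits = sum(fit_trend(year, 0.5 * year + rng.normal(0, 1, n))
                   .autocorr_flags[1] for _ in range(reps))
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_ma1_noise_flags_lag1_well_above_alpha(self):
        rng = np.random.default_rng(7)
        n, reps, theta = 30, 150, 0.6
        year = np.arange(n, dtype=float)
        hits = 0
        for _ in range(reps):
            e = rng.normal(0, 1, n + 1)
            fit = fit_trend(year, 2.0 * year + e[1:] + theta * e[:-1])
            hits += fit.autocorr_flags[1]
            if fit.autocorr_flags[1]:
                assert fit.error_model == "MA1"
                assert fit.ma1 is not None and fit.ols is not None
        assert hits / reps > 0.25

    def test_slope_recovery_under_ma1(self):
        """Known slope recovered within 3 theoretical SEs in >= 90% of reps."""
        rng = np.random.default_rng(15)
        n, beta, theta = 30, 2.0, 0.6
        year = np.arange(n, dtype=float)
        se_theory = np.sqrt(1 + theta ** 2) / (year.std() * np.sqrt(n))
        inside = 0
        reps = 60
        for _ in range(reps):
            e = rng.normal(0, 1, n + 1)
            fit = fit_trend(year, beta * year + e[1:] + theta * e[:-1])
            inside += abs(fit.slope - beta) <= 3 * se_theory
        assert inside / reps >= 0.9


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_step_down_example(self):
        # sorted (0.01, 0.03, 0.04) x multipliers (3, 2, 1) -> (0.03, 0.06,
        # 0.04), monotone-enforced to (0.03, 0.06, 0.06), mapped back
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_against_hand_rolled_step_down(self):
        def holm_by_hand(p):
            p = np.asarray(p, float)
            order = np.argsort(p)
            m = len(p)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                adj[idx] = min(1.0, running)
            return adj

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            assert holm_adjust(p) == pytest.approx(holm_by_hand(p), abs=1e-12)

    def test_adjusted_never_smaller_than_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 8)
        assert (holm_adjust(p) >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


def test_trend_suite_applies_family_adjustment():
    rng = np.random.default_rng(9)
    year = np.arange(1991, 2021)
    rows = []
    for i, var in enumerate(["a", "b", "c"]):
        for y in year:
            rows.append({"variable": var, "year": y,
                         "value": (i + 1) * y + rng.normal(0, 20)})
    fits = trend_suite(pd.DataFrame(rows))
    assert len(fits) == 3
    for f in fits:
        assert f.p_holm is not None and f.p_holm >= f.p - 1e-15
        if f.error_model == "MA1":
            assert f.autocorr_flags[1]


def welch_by_hand(a, b):
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (ma - mb) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return t, p


def bartlett_by_hand(a, b):
    k = 2
    ns = np.array([len(a), len(b)])
    vs = np.array([a.var(ddof=1), b.var(ddof=1)])
    n = ns.sum()
    sp2 = ((ns - 1) * vs).sum() / (n - k)
    num = (n - k) * np.log(sp2) - ((ns - 1) * np.log(vs)).sum()
    den = 1 + (np.sum(1 / (ns - 1)) - 1 / (n - k)) / (3 * (k - 1))
    stat = num / den
    return stat, scipy.stats.chi2.sf(stat, k - 1)


class TestCompareByBiomass:
    def frame(self, low_vals, high_vals):
        rows = []
        biomass = {}
        for i, v in enumerate(low_vals):
            rows.append({"year": 2000 + i, "age": "adult", "sex": "male",
                         "value": v})
            biomass[2000 + i] = 30.0
        for i, v in enumerate(high_vals):
            rows.append({"year": 2100 + i, "age": "adult", "sex": "male",
                         "value": v})
            biomass[2100 + i] = 90.0
        return pd.DataFrame(rows), biomass

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(12)
        low = rng.normal(1200, 80, 7)
        high = rng.normal(1250, 40, 6)
        df, bio = self.frame(low, high)
        (gc,) = compare_by_biomass(df, bio)
        t, p = welch_by_hand(low, high)
        assert gc.welch_t == pytest.approx(t, abs=1e-9)
        assert gc.welch_p == pytest.approx(p, abs=1e-9)
        stat, bp = bartlett_by_hand(low, high)
        assert gc.bartlett_stat == pytest.approx(stat, abs=1e-9)
        assert gc.bartlett_p == pytest.approx(bp, abs=1e-9)
        assert (gc.n_low, gc.n_high) == (7, 6)

    def test_variance_ratio_bartlett(self):
        """Equal means, 4x variance ratio: Bartlett flags, Welch does not."""
        rng = np.random.default_rng(5)
        low = 1200 + 2 * rng.standard_normal(7) * 40
        low = low - low.mean() + 1200
        high = 1200 + rng.standard_normal(6) * 40
        high = high - high.mean() + 1200
        df, bio = self.frame(low, high)
        (gc,) = compare_by_biomass(df, bio)
        stat, _ = bartlett_by_hand(low, high)
        assert gc.bartlett_stat == pytest.approx(stat, abs=1e-9)
        assert abs(gc.welch_t) < 1e-9 and gc.welch_p == pytest.approx(1.0)

    def test_shifted_means_powerful_at_large_n(self):
        rng = np.random.default_rng(6)
        low = rng.normal(1150, 40, 200)
        high = rng.normal(1250, 40, 200)
        df, bio = self.frame(low, high)
        (gc,) = compare_by_biomass(df, bio)
        assert gc.welch_p < 1e-3

    def test_degenerate_group_flagged(self):
        df, bio = self.frame([1200.0], [1250.0, 1260.0, 1230.0])
        (gc,) = compare_by_biomass(df, bio)
        assert gc.degenerate and np.isnan(gc.welch_t)

    def test_frame_export(self):
        rng = np.random.default_rng(8)
        df, bio = self.frame(rng.normal(0, 1, 5), rng.normal(0, 1, 5))
        out = comparisons_to_frame(compare_by_biomass(df, bio))
        assert {"age", "sex", "welch_p", "bartlett_p"} <= set(out.columns)
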