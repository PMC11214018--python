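"""Observed-data statistics: trend regressions and biomass-group comparisons.

Annual observation series (bird counts, sea level, eelgrass biomass and shoot
length) are regressed on year by ordinary least squares.  Because count-like
ecological series can violate residual independence, each fit is screened for
temporal autocorrelation: the residual autocorrelation function is compared
to the +/-1.96/sqrt(n) white-noise band at every lag, and when lag 1 is
flagged the trend is refit with a first-order moving-average, MA(1), error
structure (regression with ARMA(0,1) errors, estimated by maximum
likelihood).  p-values across the family of regressions are adjusted by
Holm's step-down procedure.

Years are split at a January eelgrass biomass threshold (60 g m^-2 by
default) and annual mean body mass and survival are compared between the
low- and high-biomass groups within each age-sex class: Welch's
unequal-variance t-test for means and Bartlett's test for homogeneity of
variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf


@dataclass
class TrendFit:
    """A year-trend regression with its autocorrelation screen."""

    variable: str
    n: int
    slope: float
    intercept: float
    r2: float
    p: float
    error_model: str                    # "iid" | "MA1"
    p_holm: float | None = None
    autocorr_flags: dict = field(default_factory=dict)
    ols: dict = field(default_factory=dict)
    ma1: dict | None = None
    degenerate: bool = False


def fit_trend(year, value=None, variable: str = "value",
              exclude=None, alpha: float = 0.05,
              max_lag: int | None = None) -> TrendFit:
    """OLS trend fit with residual-autocorrelation screening.

    ``year``/``value`` may be two arrays or a DataFrame with those columns.
    Rows with a truthy ``exclude`` flag are dropped before fitting.  If the
    lag-1 residual autocorrelation exceeds the white-noise band the reported
    fit uses MA(1) errors; both fits are retained on the result.
    """
    if value is None:
        df = year
        year = df["year"].to_numpy(dtype=float)
        value = df["value"].to_numpy(dtype=float)
        if exclude is None and "exclude_flag" in df:
            exclude = df["exclude_flag"].to_numpy()
    year = np.asarray(year, dtype=float)
    value = np.asarray(value, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        year, value = year[keep], value[keep]
    n = len(year)
    if n < 4:
        raise ValueError("need at least 4 points for a trend fit")
    if np.ptp(value) == 0.0:
        return TrendFit(variable=variable, n=n, slope=0.0,
                        intercept=float(value[0]), r2=np.nan, p=np.nan,
                        error_model="iid", degenerate=True)

    X = sm.add_constant(year)
    ols = sm.OLS(value, X).fit()
    resid = ols.resid
    nlags = max_lag if max_lag is not None else min(10, n - 2)
    if ols.ssr <= 1e-12 * np.sum((value - value.mean()) ** 2):
        # numerically exact fit: residuals carry no autocorrelation signal
        flags = {lag: False for lag in range(1, nlags + 1)}
    else:
        r = acf(resid, nlags=nlags, fft=False)
        bound = 1.96 / np.sqrt(n)
        flags = {lag: bool(abs(r[lag]) > bound) for lag in range(1, nlags + 1)}
    ols_info = {"slope": float(ols.params[1]), "intercept": float(ols.params[0]),
                "p": float(ols.pvalues[1]), "r2": float(ols.rsquared)}

    ma1_info = None
    if flags.get(1, False):
        exog = pd.DataFrame({"year": year})
        ma = ARIMA(pd.Series(value), exog=exog, order=(0, 0, 1),
                   trend="c").fit(method_kwargs={"maxiter": 200})
        fitted = ma.params["const"] + ma.params["year"] * year
        ss_res = float(np.sum((value - fitted) ** 2))
        ss_tot = float(np.sum((value - value.mean()) ** 2))
        ma1_info = {"slope": float(ma.params["year"]),
                    "intercept": float(ma.params["const"]),
                    "theta": float(ma.params["ma.L1"]),
                    "p": float(ma.pvalues["year"]),
                    "r2": max(0.0, min(1.0, 1.0 - ss_res / ss_tot))}
        chosen, model = ma1_info, "MA1"
    else:
        chosen, model = ols_info, "iid"

    return TrendFit(variable=variable, n=n, slope=chosen["slope"],
                    intercept=chosen["intercept"], r2=chosen["r2"],
                    p=chosen["p"], error_model=model, autocorr_flags=flags,
                    ols=ols_info, ma1=ma1_info)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size <= 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def trend_suite(table: pd.DataFrame, alpha: float = 0.05) -> list[TrendFit]:
    """Fit every variable in a long table and Holm-adjust across the family.

    ``table`` columns: variable, year, value, optional exclude_flag.
    Degenerate (constant) series are excluded from the adjustment family.
    """
    fits = []
    for var, sub in table.groupby("variable", sort=True):
        fits.append(fit_trend(sub.rename(columns=str), variable=str(var),
                              alpha=alpha))
    testable = [f for f in fits if not f.degenerate]
    if testable:
        adj = holm_adjust([f.p for f in testable])
        for f, a in zip(testable, adj):
            f.p_holm = float(a)
    return fits


@dataclass
class GroupComparison:
    """Low- vs high-biomass-year comparison for one age-sex class."""

    age: str
    sex: str
    rule: str
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    var_low: float
    var_high: float
    welch_t: float = np.nan
    welch_p: float = np.nan
    bartlett_stat: float = np.nan
    bartlett_p: float = np.nan
    degenerate: bool = False


def compare_by_biomass(values: pd.DataFrame, jan_biomass,
                       threshold: float = 60.0) -> list[GroupComparison]:
    """Welch and Bartlett tests between low and high biomass years per class.

    ``values``: columns year, age, sex, value (annual means per class).
    ``jan_biomass``: mapping year -> January biomass, or a DataFrame with
    columns year and jan_biomass_g_m2.  Years with biomass < threshold form
    the low group.  Classes with fewer than 2 years in either group are
    returned flagged, without test statistics.
    """
    if isinstance(jan_biomass, pd.DataFrame):
        jan_biomass = dict(zip(jan_biomass["year"],
                               jan_biomass["jan_biomass_g_m2"]))
    rule = f"January biomass < {threshold:g} g/m2"
    out = []
    for (age, sex), sub in values.groupby(["age", "sex"], sort=True):
        b = sub["year"].map(jan_biomass)
        low = sub.loc[b < threshold, "value"].to_numpy(dtype=float)
        high = sub.loc[b >= threshold, "value"].to_numpy(dtype=float)
        gc = GroupComparison(
            age=str(age), sex=str(sex), rule=rule,
            n_low=len(low), n_high=len(high),
            mean_low=float(np.mean(low)) if len(low) else np.nan,
            mean_high=float(np.mean(high)) if len(high) else np.nan,
            var_low=float(np.var(low, ddof=1)) if len(low) > 1 else np.nan,
            var_high=float(np.var(high, ddof=1)) if len(high) > 1 else np.nan,
        )
        if len(low) < 2 or len(high) < 2:
            gc.degenerate = True
        else:
            t, p = scipy.stats.ttest_ind(low, high, equal_var=False)
            gc.welch_t, gc.welch_p = float(t), float(p)
            stat, p = scipy.stats.bartlett(low, high)
            gc.bartlett_stat, gc.bartlett_p = float(stat), float(p)
        out.append(gc)
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])
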