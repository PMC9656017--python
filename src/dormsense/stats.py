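"""Exploratory statistics of the aligned dataset.

Correlation matrices (Pearson and Spearman, pairwise-complete), biased
autocorrelation curves for periodicity screening, midday/midnight monthly
aggregates, and the environmental volatility regression

    X = k1 + k2 * T + k3 * I_D

fitted per JIP parameter by ordinary least squares.  The regression is
intentionally simplistic — no cumulative-exposure terms — because its
goodness of fit is the point: a parameter with high r-squared is slaved to
transient weather and carries little information about slow dormancy
physiology, whereas a low r-squared flags a parameter whose dynamics are
internally driven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tsa.stattools import acf as _sm_acf

from .preprocessing import AlignedDataset

__all__ = [
    "CorrelationMatrix",
    "VolatilityModel",
    "VolatilityResults",
    "correlation_matrix",
    "autocorrelation",
    "monthly_aggregate",
    "fit_volatility",
    "subset_index",
]


@dataclass
class CorrelationMatrix:
    method: str
    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    n_obs: pd.DataFrame

    def __post_init__(self):
        c = self.coefficients.to_numpy(float)
        if not np.allclose(c, c.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, r, p, n) for CSV export."""
        rows = []
        cols = list(self.coefficients.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.coefficients.loc[a, b],
                        "p": self.p_values.loc[a, b],
                        "n": self.n_obs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def subset_index(dataset: AlignedDataset, subset: str) -> pd.DatetimeIndex:
    """Timestamps of a diurnal subset.

    ``midday``/``midnight`` are defined by the daily extremum of solar
    elevation (+-1 h), which is robust to timezone and daylight-saving
    conventions; ``all`` returns every timestamp.
    """
    if subset == "all":
        return dataset.timestamps
    if subset not in ("midday", "midnight"):
        raise ValueError("subset must be one of all|midday|midnight")
    elev = dataset.data["solar_elevation"]
    day_key = elev.index.floor("D")
    extremum = elev.groupby(day_key).idxmax() if subset == "midday" else elev.groupby(day_key).idxmin()
    keep = np.zeros(len(elev), dtype=bool)
    pos = elev.index.get_indexer(extremum.to_numpy())
    for p in pos:
        if p >= 0:
            keep[max(0, p - 1) : p + 2] = True
    return dataset.timestamps[keep]


def correlation_matrix(
    dataset: AlignedDataset,
    method: str = "pearson",
    subset: str = "all",
    columns: list[str] | None = None,
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix with p-values.

    p-values test the two-sided null of zero correlation.  Constant
    columns yield NaN coefficients for their pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    idx = subset_index(dataset, subset)
    df = dataset.valid().loc[idx]
    cols = list(columns) if columns is not None else list(df.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    test = sps.pearsonr if method == "pearson" else sps.spearmanr
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(df[cols[i]].notna().sum())
        for j in range(i + 1, k):
            pair = df[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_pairs:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue
            res = test(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    make = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrix(method, make(r), make(p), make(n))


def autocorrelation(series: pd.Series, max_lag_hours: int) -> pd.Series:
    """Biased sample autocorrelation, acf(0) = 1, for a gap-free uniform
    series (lags in hours)."""
    v = np.asarray(series, dtype=float)
    if np.isnan(v).any():
        raise ValueError("series has gaps; regularize first")
    if len(v) <= 2 * max_lag_hours:
        raise ValueError("series must be longer than twice the maximum lag")
    vals = _sm_acf(v, nlags=max_lag_hours, fft=True, adjusted=False)
    return pd.Series(vals, index=pd.RangeIndex(max_lag_hours + 1, name="lag_h"))


def monthly_aggregate(
    dataset: AlignedDataset,
    parameter: str,
    at: str = "midday",
    min_obs: int = 5,
) -> pd.DataFrame:
    """Calendar-month mean +- sd of one parameter in a diurnal subset.

    Months with fewer than ``min_obs`` valid observations are omitted.
    """
    idx = subset_index(dataset, at)
    s = dataset.valid(parameter).loc[idx].dropna()
    # calendar months in the dataset's own timezone (UTC internally)
    grouped = s.groupby(s.index.tz_localize(None).to_period("M"))
    out = grouped.agg(mean="mean", sd="std", n="count")
    return out[out["n"] >= min_obs]


@dataclass
class VolatilityResults:
    """OLS estimates of the environmental response of one JIP parameter."""

    parameter: str
    k1: float
    k2: float
    k3: float
    bse: np.ndarray
    r_squared: float
    rmse: float
    n_obs: int
    collinear: bool
    _sm_results: object = None

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3])

    def residuals(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    def summary(self):
        return self._sm_results.summary(
            yname=self.parameter, xname=["k1", "k2 (T)", "k3 (I_D)"]
        )

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "r2": self.r_squared,
            "rmse": self.rmse,
            "n": self.n_obs,
        }


class VolatilityModel:
    """Linear environmental-response model of one JIP parameter.

    Wraps statsmodels OLS of X on (1, air temperature, direct insolation).
    A high r-squared marks the parameter as weather-volatile; per-RC
    dissipation fluxes are expected to fit poorly outside eco-dormancy.
    """

    def __init__(self, endog: pd.Series, temperature: pd.Series, insolation: pd.Series):
        df = pd.DataFrame(
            {"x": endog, "T": temperature, "I": insolation}
        ).dropna()
        if len(df) < 10:
            raise ValueError("need at least 10 complete rows")
        self._name = endog.name or "X"
        self._df = df

    @classmethod
    def from_dataset(cls, dataset: AlignedDataset, parameter: str) -> "VolatilityModel":
        return cls(
            dataset.valid(parameter).rename(parameter),
            dataset.valid("air_T"),
            dataset.valid("insolation_direct"),
        )

    def fit(self) -> VolatilityResults:
        exog = sm.add_constant(self._df[["T", "I"]])
        res = sm.OLS(self._df["x"], exog).fit()
        corr_ti = self._df["T"].corr(self._df["I"])
        return VolatilityResults(
            parameter=self._name,
            k1=float(res.params.iloc[0]),
            k2=float(res.params.iloc[1]),
            k3=float(res.params.iloc[2]),
            bse=res.bse.to_numpy(),
            r_squared=float(res.rsquared),
            rmse=float(np.sqrt(np.mean(res.resid**2))),
            n_obs=int(res.nobs),
            collinear=bool(abs(corr_ti) > 0.999),
            _sm_results=res,
        )


def fit_volatility(dataset: AlignedDataset, parameter: str) -> VolatilityResults:
    """Convenience wrapper: fit the volatility regression for one column."""
    return VolatilityModel.from_dataset(dataset, parameter).fit()
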