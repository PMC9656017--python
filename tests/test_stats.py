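"""Correlation, autocorrelation, aggregation and the volatility regression."""

import numpy as np
import pandas as pd
import pytest

from dormsense.preprocessing import AlignedDataset
from dormsense.stats import (
    VolatilityModel,
    autocorrelation,
    correlation_matrix,
    fit_volatility,
    monthly_aggregate,
    subset_index,
)


def dataset_from(frame: pd.DataFrame, jip=()) -> AlignedDataset:
    return AlignedDataset(frame, frame.notna(), jip_columns=tuple(jip))


@pytest.fixture(scope="module")
def toy_dataset(default_season=None):
    idx = pd.date_range("2020-01-01T00:00Z", periods=2000, freq="h")
    rng = np.random.default_rng(0)
    x = rng.normal(size=2000)
    frame = pd.DataFrame(
        {
            "x": x,
            "linear": 2.0 * x + 3.0,
            "cubic": x**3,
            "noise": rng.normal(size=2000),
            "solar_elevation": np.sin(2 * np.pi * (idx.hour - 12) / 24),
        },
        index=idx,
    )
    return dataset_from(frame)


class TestCorrelationMatrix:
    def test_self_and_exact_linear(self, toy_dataset):
        cm = correlation_matrix(toy_dataset, columns=["x", "linear", "noise"])
        assert cm.coefficients.loc["x", "x"] == 1.0
        assert cm.coefficients.loc["x", "linear"] == pytest.approx(1.0)
        assert abs(cm.coefficients.loc["x", "noise"]) < 0.1
        assert cm.p_values.loc["x", "linear"] < 1e-100

    def test_spearman_saturates_on_monotone_transform(self, toy_dataset):
        sp = correlation_matrix(toy_dataset, method="spearman", columns=["x", "cubic"])
        pe = correlation_matrix(toy_dataset, method="pearson", columns=["x", "cubic"])
        # oracle: rank-transform then product-moment by direct computation
        ranks_x = pd.Series(toy_dataset.data["x"]).rank()
        ranks_c = pd.Series(toy_dataset.data["cubic"]).rank()
        direct = np.corrcoef(ranks_x, ranks_c)[0, 1]
        assert sp.coefficients.loc["x", "cubic"] == pytest.approx(direct, abs=1e-12)
        assert sp.coefficients.loc["x", "cubic"] == pytest.approx(1.0)
        assert pe.coefficients.loc["x", "cubic"] < 1.0

    def test_constant_column_gives_missing(self, toy_dataset):
        ds = toy_dataset.copy()
        ds.data["flat"] = 1.0
        ds.mask["flat"] = True
        cm = correlation_matrix(ds, columns=["x", "flat"])
        assert np.isnan(cm.coefficients.loc["x", "flat"])

    def test_symmetry_and_long_export(self, default_season):
        ds, _ = default_season
        cm = correlation_matrix(ds, columns=["Fv_over_Fm", "DI0_per_RC", "air_T"])
        c = cm.coefficients.to_numpy()
        assert np.allclose(c, c.T)
        long = cm.to_long()
        assert set(long.columns) == {"var1", "var2", "r", "p", "n"}
        assert len(long) == 3

    def test_fv_fm_tracks_temperature_in_generator(self, default_season):
        ds, _ = default_season
        cm = correlation_matrix(ds, columns=["Fv_over_Fm", "air_T"])
        assert cm.coefficients.loc["Fv_over_Fm", "air_T"] > 0.5


class TestSubsets:
    def test_midday_midnight_follow_solar_extrema(self, default_season):
        ds, _ = default_season
        midday = subset_index(ds, "midday")
        midnight = subset_index(ds, "midnight")
        elev = ds.data["solar_elevation"]
        assert elev.loc[midday].mean() > 10
        assert elev.loc[midnight].mean() < -10
        assert len(midday) < len(ds.timestamps) / 4


class TestAutocorrelation:
    def test_lag_zero_and_daily_periodicity(self):
        idx = pd.date_range("2020-01-01T00:00Z", periods=24 * 500, freq="h")
        s = pd.Series(np.sin(2 * np.pi * np.arange(len(idx)) / 24.0), index=idx)
        acf = autocorrelation(s, max_lag_hours=48)
        assert acf.iloc[0] == 1.0
        # biased estimator shrinks by (1 - k/n); negligible at this length
        assert acf.iloc[24] >= 0.99

    def test_white_noise_stays_inside_null_band(self, rng):
        n = 10000
        s = pd.Series(rng.normal(size=n))
        acf = autocorrelation(s, max_lag_hours=100)
        inside = (np.abs(acf.iloc[1:]) < 3.0 / np.sqrt(n)).mean()
        assert inside >= 0.99

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(pd.Series(np.arange(50.0)), max_lag_hours=30)


class TestMonthlyAggregate:
    def test_constant_column(self, default_season):
        ds, _ = default_season
        ds2 = ds.copy()
        ds2.data["Fv_over_Fm"] = 0.5
        out = monthly_aggregate(ds2, "Fv_over_Fm", at="midnight")
        assert np.allclose(out["mean"], 0.5)
        assert np.allclose(out["sd"], 0.0)

    def test_matches_independent_groupby(self, default_season):
        ds, _ = default_season
        out = monthly_aggregate(ds, "DI0_per_RC", at="midday")
        idx = subset_index(ds, "midday")
        s = ds.valid("DI0_per_RC").loc[idx].dropna()
        ref = s.groupby(s.index.tz_localize(None).to_period("M")).mean()
        assert np.allclose(out["mean"], ref.loc[out.index])
        assert (out["n"] >= 5).all()


class TestVolatilityFit:
    @staticmethod
    def env_frame(n, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2020-01-01T00:00Z", periods=n, freq="h")
        return idx, rng.normal(10, 8, n), np.clip(rng.normal(0.3, 0.25, n), 0, None), rng

    def test_noiseless_recovery_is_exact(self):
        idx, T, I, _ = self.env_frame(500)
        x = 0.7 + 0.004 * T - 0.1 * I
        frame = pd.DataFrame({"Fv_over_Fm": x, "air_T": T, "insolation_direct": I}, index=idx)
        fit = fit_volatility(dataset_from(frame, jip=["Fv_over_Fm"]), "Fv_over_Fm")
        assert fit.k == pytest.approx([0.7, 0.004, -0.1], rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse < 1e-12

    def test_pure_noise_has_no_explained_variance(self):
        idx, T, I, rng = self.env_frame(5000, seed=1)
        frame = pd.DataFrame(
            {"X": rng.normal(size=5000), "air_T": T, "insolation_direct": I}, index=idx
        )
        fit = fit_volatility(dataset_from(frame, jip=["X"]), "X")
        assert fit.r_squared < 0.05

    def test_half_noise_gives_half_r_squared(self):
        """With noise variance equal to signal variance, r^2 = 0.5 by the
        variance-decomposition identity."""
        idx, T, I, rng = self.env_frame(5000, seed=2)
        signal = 0.004 * T - 0.1 * I
        noise = rng.normal(0, signal.std(), 5000)
        frame = pd.DataFrame(
            {"X": 0.7 + signal + noise, "air_T": T, "insolation_direct": I}, index=idx
        )
        fit = fit_volatility(dataset_from(frame, jip=["X"]), "X")
        assert fit.r_squared == pytest.approx(0.5, abs=0.05)

    def test_residuals_orthogonal_to_regressors(self, default_season):
        ds, _ = default_season
        fit = fit_volatility(ds, "Fv_over_Fm")
        resid = fit.residuals()
        T = ds.data["air_T"].to_numpy()
        I = ds.data["insolation_direct"].to_numpy()
        n = len(resid)
        assert abs(resid.sum()) / n < 1e-8
        assert abs(np.dot(resid, T)) / n < 1e-6
        assert abs(np.dot(resid, I)) / n < 1e-8

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (500, 5000):
            reps = []
            for seed in range(5):
                idx, T, I, rng = self.env_frame(n, seed=100 + seed)
                x = 1.0 + 0.01 * T + 0.6 * I + rng.normal(0, 0.2, n)
                frame = pd.DataFrame({"X": x, "air_T": T, "insolation_direct": I}, index=idx)
                fit = fit_volatility(dataset_from(frame, jip=["X"]), "X")
                reps.append(np.abs(fit.k - np.array([1.0, 0.01, 0.6])))
            errs[n] = np.mean(reps, axis=0)
        assert np.all(errs[5000] <= errs[500])

    def test_summary_and_model_class(self, default_season):
        ds, _ = default_season
        res = VolatilityModel.from_dataset(ds, "DI0_per_RC").fit()
        text = str(res.summary())
        assert "k2 (T)" in text and "k3 (I_D)" in text
        assert not res.collinear
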