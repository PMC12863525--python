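"""HAC sandwich correctness (brute-force and statsmodels cross-checks),
exact affine fits, Bonferroni arithmetic, and the diurnal-range regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.sandwich_covariance import cov_hac_simple, cov_nw_groupsum

from reeftherm import regression
from reeftherm.synthetic import simulate_paired_series, simulate_paired_panel


def brute_force_nw(X, u, lag):
    """Textbook double sum: Omega = sum_s sum_t w_|s-t| g_s g_t'."""
    n, k = X.shape
    g = X * u[:, None]
    omega = np.zeros((k, k))
    for s in range(n):
        for t in range(n):
            l = abs(s - t)
            if l <= lag:
                w = 1.0 - l / (lag + 1.0)
                omega += w * np.outer(g[s], g[t])
    bread = np.linalg.inv(X.T @ X)
    return bread @ omega @ bread


@pytest.fixture(scope="module")
def fixed_dataset():
    data = simulate_paired_series(50, seed=123, bias=0.3, sigma_error=0.4)
    x = data["ssst"].to_numpy()
    y = data["insitu"].to_numpy()
    X = np.column_stack([np.ones(50), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X, y - X @ beta


class TestHacCovariance:
    def test_matches_bruteforce_double_sum(self, fixed_dataset):
        X, u = fixed_dataset
        mine = regression.hac_covariance(X, u, "newey_west", lag=3)
        assert np.abs(mine - brute_force_nw(X, u, 3)).max() < 1e-10

    def test_lag_zero_equals_white_sandwich(self, fixed_dataset):
        X, u = fixed_dataset
        mine = regression.hac_covariance(X, u, "newey_west", lag=0)
        bread = np.linalg.inv(X.T @ X)
        white = bread @ (X * (u**2)[:, None]).T @ X @ bread
        assert np.array_equal(mine, regression._psd_floor(white)) or np.allclose(
            mine, white, atol=1e-15
        )

    def test_matches_statsmodels_nw(self, fixed_dataset):
        X, u = fixed_dataset
        res = sm.OLS(X @ [0, 0] + u, X).fit()  # residuals of this fit equal u
        theirs = cov_hac_simple(res, nlags=4, use_correction=False)
        mine = regression.hac_covariance(X, res.resid, "newey_west", lag=4)
        assert np.allclose(mine, theirs, atol=1e-14)

    def test_matches_statsmodels_driscoll_kraay(self):
        panels = simulate_paired_panel(60, seed=5)
        stacked = pd.concat(panels.values()).sort_index(kind="mergesort")
        x = stacked["ssst"].to_numpy()
        y = stacked["insitu"].to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        res = sm.OLS(y, X).fit()
        time_codes = pd.factorize(stacked.index)[0]
        theirs = cov_nw_groupsum(res, nlags=3, time=time_codes, use_correction=False)
        mine = regression.hac_covariance(
            X, res.resid, "driscoll_kraay", lag=3, time_ids=stacked.index.to_numpy()
        )
        assert np.allclose(mine, theirs, atol=1e-14)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 40
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            u = rng.normal(size=n)
            for est, tid in (("newey_west", None), ("driscoll_kraay", np.arange(n) // 2)):
                cov = regression.hac_covariance(X, u, est, lag=5, time_ids=tid)
                assert np.allclose(cov, cov.T)
                assert np.linalg.eigvalsh(cov).min() >= -1e-15

    def test_lag_not_smaller_than_series_rejected(self, fixed_dataset):
        X, u = fixed_dataset
        with pytest.raises(ValueError, match="lag"):
            regression.hac_covariance(X, u, "newey_west", lag=50)

    def test_iid_data_hac_close_to_classical_ols(self):
        """On iid homoskedastic data the HAC correction should be a no-op
        to within Monte-Carlo error."""
        ratios = []
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = 2000
            x = rng.normal(size=n)
            y = 1.0 + x + rng.normal(0, 0.5, size=n)
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            u = y - X @ beta
            cov = regression.hac_covariance(X, u, "newey_west", lag=regression.auto_lag(n))
            s2 = u @ u / (n - 2)
            cov_ols = s2 * np.linalg.inv(X.T @ X)
            ratios.append(np.sqrt(cov[1, 1] / cov_ols[1, 1]))
        assert abs(np.mean(ratios) - 1.0) < 0.1


class TestFitComparisonRegression:
    def test_exact_identity_relation(self):
        data = simulate_paired_series(200, seed=1, sigma_error=0.0)
        res = regression.fit_comparison_regression(data, scope="Northern")
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.p_slope == pytest.approx(1.0)
        assert res.p_intercept == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)
        assert res.mean_difference == pytest.approx(0.0, abs=1e-10)
        assert res.estimator == "newey_west"

    def test_constructed_bias_shift(self):
        data = simulate_paired_series(200, seed=2, bias=0.58, sigma_error=0.0)
        res = regression.fit_comparison_regression(data)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.58, abs=1e-10)
        assert res.mean_difference == pytest.approx(0.58, abs=1e-10)

    def test_affine_recovery_to_machine_precision(self):
        data = simulate_paired_series(100, seed=4, slope=1.7, bias=-0.9, sigma_error=0.0)
        res = regression.fit_comparison_regression(data)
        assert res.slope == pytest.approx(1.7, abs=1e-12)
        assert res.intercept == pytest.approx(-0.9, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_identity(self):
        data = simulate_paired_series(300, seed=5)
        res = regression.fit_comparison_regression(data)
        assert res.pearson_r**2 == pytest.approx(res.r2, abs=1e-12)

    def test_all_scope_uses_driscoll_kraay(self):
        panels = simulate_paired_panel(100, seed=6)
        res = regression.fit_comparison_regression(panels, scope="all")
        assert res.estimator == "driscoll_kraay"
        assert res.n == 300
        assert res.df_resid == 98  # dates - 2

    def test_too_few_rows_and_zero_variance_rejected(self):
        short = simulate_paired_series(12, seed=0).iloc[:5]
        with pytest.raises(ValueError, match="10"):
            regression.fit_comparison_regression(short)
        flat = simulate_paired_series(50, seed=0)
        flat["ssst"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            regression.fit_comparison_regression(flat)

    def test_hac_rejects_less_than_naive_under_null(self):
        """Quick calibration sanity check (full study in acceptance tests)."""
        out = regression.calibration_study("newey_west", n=300, n_reps=150, seed=9)
        assert out["hac_rejection"] < out["ols_rejection"]


class TestBonferroni:
    def test_family_of_four_arithmetic(self):
        adj = regression.bonferroni_adjust([0.01, 0.5, 0.0125, 0.3])
        assert adj[0] == pytest.approx(0.04)
        assert adj[1] == 1.0  # capped
        assert adj[2] == pytest.approx(0.05)

    def test_wrong_family_size_needs_override(self):
        with pytest.raises(ValueError, match="family"):
            regression.bonferroni_adjust([0.01, 0.02])
        assert regression.bonferroni_adjust([0.01], family_size=1) == [0.01]

    def test_adjust_family_attaches_values(self):
        results = {
            s: regression.fit_comparison_regression(simulate_paired_series(60, seed=i))
            for i, s in enumerate(["all", "Northern", "Western", "Southern"])
        }
        regression.adjust_family(results)
        for r in results.values():
            assert r.p_slope_adj == pytest.approx(min(1.0, 4 * r.p_slope))


class TestDiurnalVariabilityRegression:
    def test_independent_range_shows_no_relation(self):
        slopes, covered = [], 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            idx = pd.date_range("2018-01-01", periods=300)
            rng_range = pd.Series(0.8 + rng.normal(0, 0.2, 300), index=idx)
            ssst = pd.Series(29.0 + rng.normal(0, 0.5, 300), index=idx)
            res = regression.diurnal_variability_regression(rng_range, ssst)
            slopes.append(res.slope)
            ci = 1.96 * res.se_slope
            covered += abs(res.slope) <= ci
        assert abs(np.mean(slopes)) < 0.02
        assert covered >= 40  # CI covers the true slope of 0 most of the time

    def test_linear_dependence_recovered(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2018-01-01", periods=2000)
        ssst = pd.Series(29.0 + rng.normal(0, 1.0, 2000), index=idx)
        drange = 0.5 * ssst + rng.normal(0, 0.1, 2000)
        res = regression.diurnal_variability_regression(drange, ssst)
        assert res.slope == pytest.approx(0.5, abs=0.02)
        assert res.slope_null == 0.0

    def test_constant_range_degenerate_flag(self):
        idx = pd.date_range("2018-01-01", periods=100)
        res = regression.diurnal_variability_regression(
            pd.Series(0.75, index=idx), pd.Series(np.linspace(28, 30, 100), index=idx)
        )
        assert res.degenerate
        assert res.slope == 0.0
        assert np.isnan(res.pearson_r)


class TestDhwComparisonRegression:
    def test_identical_series(self):
        idx = pd.date_range("2020-01-01", periods=120)
        dhw = pd.Series(np.clip(np.sin(np.arange(120) / 20.0), 0, None) * 3, index=idx)
        res = regression.dhw_comparison_regression(dhw, dhw.copy())
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_doubled_accumulation_detected(self):
        rng = np.random.default_rng(2)
        idx = pd.date_range("2020-01-01", periods=500)
        base = pd.Series(np.clip(np.sin(np.arange(500) / 40.0), 0, None) * 2, index=idx)
        insitu = 2 * base + rng.normal(0, 0.05, 500)
        res = regression.dhw_comparison_regression(insitu, base)
        assert res.slope == pytest.approx(2.0, abs=0.05)
        assert res.t_slope > 2.0  # significantly above the 1:1 line
        assert res.p_slope < 0.05

    def test_amplified_insitu_accumulation_gives_slope_above_one(self):
        """When in situ anomalies run hotter than the satellite's (beyond a
        constant offset absorbed by the MMM adjustment), in situ DHW
        accumulates faster and the DHW-vs-DHW slope exceeds 1."""
        from reeftherm import metrics

        rng = np.random.default_rng(8)
        dates = pd.date_range("2019-01-01", "2020-12-31", freq="D")
        base, amp = 28.8, 1.2
        seasonal = base + amp * np.cos(2 * np.pi * (dates.dayofyear - 196) / 365.25)
        pulse = np.where(
            (dates >= pd.Timestamp("2020-06-15")) & (dates <= pd.Timestamp("2020-08-15")),
            1.5, 0.0,
        )
        ssst = pd.Series(seasonal + pulse + rng.normal(0, 0.05, len(dates)), index=dates)
        insitu = base + 0.58 + 1.3 * (ssst - base) + rng.normal(0, 0.05, len(dates))
        ssst_mmm = metrics.compute_mmm(ssst, evaluation_month="2019-12")
        offset = metrics.monthly_offset(insitu.loc[:"2019-12-31"], ssst.loc[:"2019-12-31"])
        insitu_mmm = metrics.adjust_insitu_mmm(ssst_mmm, offset)
        prof_in = metrics.compute_dhw(insitu, insitu_mmm)
        prof_sat = metrics.compute_dhw(ssst, ssst_mmm)
        res = regression.dhw_comparison_regression(prof_in.dhw_defined, prof_sat.dhw_defined)
        assert prof_in.dhw.max() > prof_sat.dhw.max() > 0
        assert res.slope > 1.0

    def test_zero_variance_predictor_rejected(self):
        idx = pd.date_range("2020-01-01", periods=100)
        with pytest.raises(ValueError):
            regression.dhw_comparison_regression(
                pd.Series(1.0, index=idx), pd.Series(0.0, index=idx)
            )
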