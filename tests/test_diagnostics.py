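import numpy as np
import pytest
from scipy import stats

from contits.diagnostics import (deterministic_battery, fisher_period,
                                 jarque_bera, kpss, ljung_box, mann_kendall,
                                 mann_whitney_jump, seasonal_mann_kendall)
from contits.series_core import TimeSeries, ValidationError
from contits.synthetic import generate_arma

from _oracles import fisher_f_statistic, mk_statistic, mw_exact_pvalue, \
    mw_statistic, smk_statistic


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall(np.arange(1.0, 21.0))
        assert res.details["MK"] == 190  # N(N-1)/2 with every sign +1
        assert res.reject

    def test_constant_series(self):
        res = mann_kendall(np.full(20, 3.0))
        assert res.details["MK"] == 0
        assert res.statistic == 0.0
        assert not res.reject

    def test_reversal_antisymmetry(self, rng):
        x = rng.normal(size=40)
        assert mann_kendall(x).statistic == pytest.approx(
            -mann_kendall(x[::-1]).statistic, abs=1e-12)

    def test_needs_four_points(self):
        with pytest.raises(ValidationError):
            mann_kendall([1.0, 2.0, 3.0])


class TestSeasonalMannKendall:
    def test_all_seasons_increasing(self):
        t = np.arange(48.0)
        res = seasonal_mann_kendall(t, omega=12)
        assert res.reject

    def test_omega_one_delegates(self, rng):
        x = rng.normal(size=40)
        assert seasonal_mann_kendall(x, omega=1).statistic == pytest.approx(
            mann_kendall(x).statistic)

    def test_brute_force_agreement(self, rng):
        for _ in range(20):
            x = rng.normal(size=36)
            res = seasonal_mann_kendall(x, omega=4)
            assert res.statistic == pytest.approx(smk_statistic(x, 4), abs=1e-10)


class TestMannWhitney:
    def test_maximal_separation_small_sample(self):
        x = np.array([1.0, 1, 1, 9, 9, 9])
        res = mann_whitney_jump(x, 3, alpha=0.05)
        # statistic matches the brute-force rank-sum form exactly
        assert res.statistic == pytest.approx(mw_statistic(x, 3), abs=1e-12)
        # the exact permutation p for n1=n2=3 is 0.10; our normal
        # approximation sits just under 0.05, so the declared rule rejects
        assert mw_exact_pvalue(x, 3) == pytest.approx(0.10, abs=1e-9)
        assert res.reject == (res.p_value < 0.05)

    def test_constant_series_symmetric(self):
        res = mann_whitney_jump(np.full(10, 2.0), 5)
        assert res.statistic == 0.0
        assert not res.reject

    def test_split_bounds(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValidationError):
            mann_whitney_jump(x, 1)
        with pytest.raises(ValidationError):
            mann_whitney_jump(x, 19)


class TestFisher:
    def test_planted_sinusoid_detected(self, rng):
        t = np.arange(1, 61)
        x = 5 * np.sin(2 * np.pi * 5 * t / 60) + 0.1 * rng.normal(size=60)
        res = fisher_period(x)
        assert res.reject
        assert res.details["harmonic"] == 5

    def test_critical_value_for_n59(self):
        res = fisher_period(np.sin(np.arange(59.0)) + np.arange(59.0) * 0.01)
        # F(2, 57) 5% point: near the conventional rounded threshold of 3
        assert res.critical_value == pytest.approx(
            stats.f.ppf(0.95, 2, 57), rel=1e-9)
        assert 3.0 < res.critical_value < 3.4


class TestKpss:
    def test_stationary_ar1_mostly_passes(self):
        passes = 0
        for s in range(60):
            x = generate_arma(200, phi=(0.3,), sd=1.0, seed=s)
            passes += not kpss(x, "level").reject
        assert passes >= 54  # >= 90%

    def test_random_walk_mostly_rejects(self, rng):
        rejects = 0
        for s in range(60):
            r = np.random.default_rng(s)
            x = np.cumsum(r.normal(size=200))
            rejects += kpss(x, "level").reject
        assert rejects >= 54

    def test_zero_lag_matches_defining_sum(self, rng):
        x = rng.normal(size=50)
        res = kpss(x, "level", truncation_lag=0)
        e = x - x.mean()
        s_t = np.cumsum(e)
        eta = np.sum(s_t ** 2) / (50 ** 2 * np.mean(e ** 2))
        assert res.statistic == pytest.approx(eta, rel=1e-10)

    def test_lag_bound(self, rng):
        with pytest.raises(ValidationError):
            kpss(rng.normal(size=20), "level", truncation_lag=20)


class TestJarqueBera:
    def test_zero_at_normal_moment_point(self):
        # a symmetric two-point-mixture-free sample with exact S=0, K=3 is
        # hard to construct; verify the formula's zero point algebraically
        # through a sample engineered to have those moments
        x = np.array([-1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.2, -1.2])
        res = jarque_bera(x)
        sk, ku = res.details["skewness"], res.details["kurtosis"]
        expected = 8 * (sk ** 2 / 6 + (ku - 3) ** 2 / 24)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_exponential_rejected(self):
        hits = 0
        for s in range(50):
            x = np.random.default_rng(s).exponential(size=500)
            hits += jarque_bera(x).reject
        assert hits >= 49

    def test_zero_variance_error(self):
        with pytest.raises(ValidationError):
            jarque_bera(np.full(20, 1.0))


class TestLjungBox:
    def test_default_lag_rule(self, rng):
        res = ljung_box(rng.normal(size=50))
        assert res.details["m"] == 4  # round(ln 50)

    def test_ar1_residuals_rejected(self):
        hits = 0
        for s in range(40):
            x = generate_arma(200, phi=(0.6,), sd=1.0, seed=100 + s)
            hits += ljung_box(x).reject
        assert hits >= 38  # >= 95%

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import acorr_ljungbox
        x = rng.normal(size=120)
        res = ljung_box(x, n_lags=6)
        sm = acorr_ljungbox(x, lags=[6])
        assert res.statistic == pytest.approx(float(sm["lb_stat"].iloc[0]),
                                              rel=1e-8)

    def test_lag_errors(self, rng):
        with pytest.raises(ValidationError):
            ljung_box(rng.normal(size=20), n_lags=20)


class TestBruteForceAgreement:
    """Statistics match naive double-loop transcriptions of their defining
    sums on short random series (with and without ties)."""

    def test_mk_mw_fisher(self, rng):
        for i in range(30):
            n = int(rng.integers(12, 31))
            x = rng.normal(size=n)
            if i % 3 == 0:
                x = np.round(x, 1)  # induce ties
            assert mann_kendall(x).statistic == pytest.approx(
                mk_statistic(x), abs=1e-10)
            split = n // 2
            assert mann_whitney_jump(x, split).statistic == pytest.approx(
                mw_statistic(x, split), abs=1e-10)
            assert fisher_period(x).statistic == pytest.approx(
                fisher_f_statistic(x), rel=1e-10)


class TestBattery:
    def test_planted_trend_flagged(self):
        flags = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = 0.08 * np.arange(120.0) + rng.normal(size=120)
            rep = deterministic_battery(TimeSeries(x, period=12))
            flags.append(rep.verdicts["trend"])
        assert np.mean(flags) >= 0.9

    def test_white_noise_mostly_clean(self):
        clean = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            rep = deterministic_battery(TimeSeries(rng.normal(size=120), period=12))
            v = rep.verdicts
            clean.append(not v["trend"] and not v["jump"] and not v["period"]
                         and v["stationary"] and v["normal"])
        assert np.mean(clean) >= 0.6  # majority over replicates

    def test_differencing_clears_trend_flag(self, rng):
        x = 0.5 * np.arange(100.0) + rng.normal(size=100)
        rep = deterministic_battery(TimeSeries(np.diff(x)))
        assert not rep.verdicts["trend"]

    def test_errors_propagate_without_stopping(self):
        # constant series: JB errors, MK decides 'no trend'; battery continues
        rep = deterministic_battery(TimeSeries(np.full(30, 5.0)))
        assert "jarque_bera" in rep.errors
        assert rep.results["mann_kendall"] is not None
        assert not rep.verdicts["trend"]

    def test_report_table_shape(self, white_noise):
        rep = deterministic_battery(white_noise)
        df = rep.to_frame()
        assert set(df["test"]) >= {"mann_kendall", "mann_whitney", "fisher",
                                   "kpss", "jarque_bera"}
        d = rep.to_dict()
        assert "verdicts" in d and "tests" in d


class TestBatteryTable:
    def test_variant_rows_and_test_columns(self):
        from contits.diagnostics import battery_table
        from contits.synthetic import generate_ace_like
        df = battery_table(generate_ace_like(2))
        assert list(df["series"]) == ["main", "detrended", "differenced"]
        assert "mann_kendall" in df.columns and "kpss" in df.columns
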