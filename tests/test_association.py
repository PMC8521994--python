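import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from aidlog import (
    LogTable,
    StudyConfig,
    daily_acoustics,
    fit_usage_lmm,
    lrt_vs_null,
    participant_zscore,
    prepare_model_frame,
    spl_leq,
    standardize_pooled,
    variance_explained,
    vif,
)
from aidlog.association import Z_COLUMNS, _fit_mixedlm, _vc_formulas

from conftest import make_log_frame


class TestDailyAcoustics:
    def _table(self, spl_values, snr_values=None):
        snr_values = snr_values if snr_values is not None else [5.0] * len(spl_values)
        rows = [
            ("P1", "left", pd.Timestamp("2019-06-03 10:00") + pd.Timedelta(minutes=i), 60 * (i + 1), s, n)
            for i, (s, n) in enumerate(zip(spl_values, snr_values))
        ]
        return LogTable(make_log_frame(rows))

    def test_two_minute_leq_hand_value(self):
        # 10*log10((10^6 + 10^7)/2)
        assert spl_leq([60.0, 70.0]) == pytest.approx(67.4036, abs=1e-3)

    def test_constant_day_degenerates(self, cfg):
        out = daily_acoustics(self._table([65.0] * 12), cfg)
        row = out.iloc[0]
        assert row["spl_leq_db"] == pytest.approx(65.0)
        assert row["spl_sd_db"] == 0.0

    def test_snr_median(self, cfg):
        out = daily_acoustics(self._table([65.0] * 12, [2.0, 3.0, 9.0] * 4), cfg)
        assert out.iloc[0]["snr_median_db"] == 3.0

    def test_short_days_excluded(self, cfg):
        out = daily_acoustics(self._table([65.0] * 5), cfg)
        assert out.empty
        assert out.attrs["n_excluded_short_days"] == 1

    def test_leq_at_least_arithmetic_mean(self, cfg, default_cohort):
        table, _ = default_cohort
        out = daily_acoustics(table, cfg)
        df = table.data
        means = (
            df.groupby(["participant_id", df["timestamp"].dt.date, "side"])["spl_db"]
            .mean()
            .to_numpy()
        )
        # energetic mean inequality, day by day (same grouping order)
        grouped_n = df.groupby(["participant_id", df["timestamp"].dt.date, "side"]).size()
        keep = (grouped_n >= 10).to_numpy()
        assert (out["spl_leq_db"].to_numpy() >= means[keep] - 1e-9).all()

    def test_permutation_invariance(self, cfg):
        rng = np.random.default_rng(0)
        spl = list(60 + 8 * rng.random(30))
        snr = list(rng.normal(4, 2, 30))
        a = daily_acoustics(self._table(spl, snr), cfg)
        perm = rng.permutation(30)
        b = daily_acoustics(
            self._table([spl[i] for i in perm], [snr[i] for i in perm]), cfg
        )
        for col in ("spl_leq_db", "spl_sd_db", "snr_median_db"):
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col])

    def test_constant_offset_shifts_leq_not_sd(self, cfg):
        rng = np.random.default_rng(1)
        spl = list(60 + 8 * rng.random(30))
        a = daily_acoustics(self._table(spl), cfg)
        b = daily_acoustics(self._table([s + 7.0 for s in spl]), cfg)
        assert b.iloc[0]["spl_leq_db"] == pytest.approx(a.iloc[0]["spl_leq_db"] + 7.0)
        assert b.iloc[0]["spl_sd_db"] == pytest.approx(a.iloc[0]["spl_sd_db"])


class TestParticipantZscore:
    def _daily(self, pid_values):
        rows = []
        for pid, values in pid_values.items():
            for i, v in enumerate(values):
                rows.append((pid, f"2019-06-{i+1:02d}", v))
        return pd.DataFrame(rows, columns=["participant_id", "date", "spl_leq_db"])

    def test_three_values(self):
        out = participant_zscore(self._daily({"P1": [1.0, 2.0, 3.0]}), ["spl_leq_db"])
        np.testing.assert_allclose(out["spl_leq_db"], [-1.0, 0.0, 1.0])

    def test_constant_values_flagged(self):
        out = participant_zscore(self._daily({"P1": [5.0, 5.0, 5.0]}), ["spl_leq_db"])
        assert out["zscore_flagged"].all()
        np.testing.assert_allclose(out["spl_leq_db"], 0.0)

    def test_affine_invariance(self):
        vals = [3.0, 7.0, 1.0, 9.0]
        a = participant_zscore(self._daily({"P1": vals}), ["spl_leq_db"])
        b = participant_zscore(
            self._daily({"P1": [2.5 * v + 4 for v in vals]}), ["spl_leq_db"]
        )
        np.testing.assert_allclose(a["spl_leq_db"], b["spl_leq_db"])

    def test_too_few_days_passed_through(self):
        out = participant_zscore(self._daily({"P1": [1.0, 2.0]}), ["spl_leq_db"])
        assert out["zscore_flagged"].all()
        np.testing.assert_allclose(out["spl_leq_db"], [1.0, 2.0])


class TestVif:
    def test_orthogonal_columns_unity(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        assert (vif(X) < 1.01).all()

    def test_duplicated_column_infinite(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(0).normal(size=10)})
        out = vif(X)
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_known_correlation_closed_form(self):
        # r = 0.8 pair with an independent third column: VIF = 1/(1-0.64)
        rng = np.random.default_rng(1)
        n = 200_000
        z = rng.normal(size=n)
        a = 0.8 * z + 0.6 * rng.normal(size=n)  # corr(a, z) = 0.8 exactly in law
        X = pd.DataFrame({"a": a, "b": z, "c": rng.normal(size=n)})
        out = vif(X)
        assert out["a"] == pytest.approx(1 / (1 - 0.64), rel=0.02)
        assert out["c"] == pytest.approx(1.0, abs=0.01)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": np.ones(5), "b": np.arange(5.0)})
        with pytest.raises(ValueError):
            vif(X)


def _linear_frame(n_participants=12, n_days=10, beta=(0.9, 1.3, -1.0), seed=0,
                  re_sd=1.5, resid_sd=2.0):
    """Day-level frame drawn from an explicit linear mixed model."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"P{p:02d}"
        u = rng.normal(0, re_sd)
        for d in range(n_days):
            x = rng.normal(size=3)
            y = 8 + u + float(np.dot(beta, x)) + rng.normal(0, resid_sd)
            rows.append((pid, f"2019-06-{d+1:02d}", "left", y, *x))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "date", "side", "usage_h", "leq_z", "splsd_z", "snr_z"],
    )
    df["dow"] = pd.to_datetime(df["date"]).dt.dayofweek
    df["pid_date"] = df["participant_id"] + "|" + df["date"]
    return df


class TestLmm:
    def test_reduces_to_ols_without_random_structure(self):
        """With no random-effect variance in the data, betas match OLS closely."""
        frame = _linear_frame(re_sd=0.0, resid_sd=1.0, seed=3)
        res = fit_usage_lmm(frame, slope_groups=(), day_component=False)
        X = sm.add_constant(frame[["leq_z", "splsd_z", "snr_z"]])
        ols = sm.OLS(frame["usage_h"], X).fit()
        np.testing.assert_allclose(
            res.beta.to_numpy(), ols.params[["leq_z", "splsd_z", "snr_z"]], atol=1e-4
        )

    def test_full_equals_null_lrt_is_zero(self):
        frame = _linear_frame(seed=4)
        vc = _vc_formulas((), day_component=False)
        fit = _fit_mixedlm(frame, "usage_h ~ 1", vc)
        chi2, df, p = lrt_vs_null(fit, fit)
        assert chi2 == 0.0 and p == 1.0

    def test_row_mismatch_raises(self):
        frame = _linear_frame(seed=5)
        vc = _vc_formulas((), day_component=False)
        f1 = _fit_mixedlm(frame, "usage_h ~ 1", vc)
        f2 = _fit_mixedlm(frame.iloc[:-3], "usage_h ~ 1", vc)
        with pytest.raises(ValueError):
            lrt_vs_null(f1, f2)

    def test_recovers_known_betas(self):
        frame = _linear_frame(beta=(0.9, 1.3, -1.0), n_participants=20, n_days=12, seed=6)
        res = fit_usage_lmm(frame, day_component=False)
        assert res.beta["leq_z"] == pytest.approx(0.9, abs=0.45)
        assert res.beta["splsd_z"] == pytest.approx(1.3, abs=0.45)
        assert res.beta["snr_z"] == pytest.approx(-1.0, abs=0.45)
        assert res.lrt_df == 12
        assert res.lrt_p < 0.001

    def test_variance_explained_degenerate_limits(self):
        # strong fixed effects, no random variance: marginal ~ conditional ~ OLS R2
        frame = _linear_frame(re_sd=0.0, resid_sd=0.5, seed=7)
        res = fit_usage_lmm(frame, slope_groups=(), day_component=False)
        X = sm.add_constant(frame[["leq_z", "splsd_z", "snr_z"]])
        ols_r2 = sm.OLS(frame["usage_h"], X).fit().rsquared
        assert res.r2_marginal == pytest.approx(ols_r2, abs=0.02)
        assert res.r2_conditional == pytest.approx(res.r2_marginal, abs=0.02)
        # zero fixed effects, strong random intercepts: marginal ~ 0 < conditional
        frame2 = _linear_frame(beta=(0, 0, 0), re_sd=3.0, resid_sd=1.0, seed=8)
        res2 = fit_usage_lmm(frame2, slope_groups=(), day_component=False)
        assert res2.r2_marginal < 0.05
        assert res2.r2_conditional > res2.r2_marginal + 0.3
        assert res2.r2_marginal <= res2.r2_conditional <= 1.0


class TestPaperRegime:
    """Pipeline behavior on cohorts at the generator's calibrated defaults."""

    def test_variance_explained_near_published_regime(self, regime_fits):
        # acoustics alone ~15% of day-to-day usage variance; full model ~35%
        r2m = np.mean([r.r2_marginal for r in regime_fits])
        r2c = np.mean([r.r2_conditional for r in regime_fits])
        assert r2m == pytest.approx(0.15, abs=0.07)
        assert r2c == pytest.approx(0.35, abs=0.07)
        for r in regime_fits:
            assert r.r2_marginal <= r.r2_conditional <= 1.0

    def test_predictors_nearly_collinearity_free(self, regime_fits):
        # published analyses report VIFs well under 2
        for r in regime_fits:
            assert (r.vif >= 1.0).all()
            assert (r.vif < 2.0).all()

    def test_intercept_only_lrt_has_default_df(self, regime_fits):
        for r in regime_fits:
            assert r.lrt_df == 12
            assert r.converged


class TestPreparedPipeline:
    def test_prepare_model_frame_columns(self, cfg, default_cohort):
        from aidlog import daily_usage, filter_day_window

        table, _ = default_cohort
        table, _ = filter_day_window(table, cfg)
        du = daily_usage(table, cfg)
        ac = daily_acoustics(table, cfg)
        frame = prepare_model_frame(du, ac)
        assert set(Z_COLUMNS) <= set(frame.columns)
        for z in Z_COLUMNS:
            assert frame[z].mean() == pytest.approx(0.0, abs=1e-9)
            assert frame[z].std(ddof=1) == pytest.approx(1.0, rel=1e-9)
        assert {"usage_h", "dow", "pid_date"} <= set(frame.columns)
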