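import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from storkmig import models
from storkmig.synthetic import simulate_model_data


class TestScaleDates:
    def test_arithmetic_example(self):
        scaled, (mu, sd) = models.scale_dates([200.0, 210.0, 220.0])
        np.testing.assert_allclose(scaled, [-1.0, 0.0, 1.0])  # sample SD = 10
        assert (mu, sd) == (210.0, 10.0)

    def test_zero_mean_unit_sd(self):
        scaled, _ = models.scale_dates([201, 215, 230, 240, 255])
        assert scaled.mean() == pytest.approx(0.0, abs=1e-12)
        assert scaled.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_inverse_recovers_inputs(self):
        d = np.array([203.0, 251.0, 277.0])
        scaled, (mu, sd) = models.scale_dates(d)
        np.testing.assert_allclose(scaled * sd + mu, d, atol=1e-9)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            models.scale_dates([210.0, 210.0, 210.0])


class TestVif:
    def test_orthogonal_covariates(self):
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        v = models.vif(df, ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=0.01)

    def test_duplicated_covariate_infinite(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        df["b"] = df["a"]
        v = models.vif(df, ["a", "b"])
        assert np.isinf(v["a"]) or v["a"] > 1e6

    def test_known_correlation_closed_form(self):
        # VIF = 1 / (1 - r^2); construct an exactly 0.8-correlated pair
        rng = np.random.default_rng(1)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        v = models.vif(pd.DataFrame({"a": a, "b": b}), ["a", "b"])
        assert v["a"] == pytest.approx(1.0 / (1.0 - 0.64), rel=0.02)


class TestNakagawaR2:
    def _fit(self, vf, vr, ve):
        return models.ModelFit(response="y", family="gaussian",
                               terms=pd.DataFrame(), vcomp={"bird": vr},
                               resid_var=ve, precision=None, r2_marginal=None,
                               r2_conditional=None, var_fixed=vf)

    def test_known_variance_partition(self):
        m, c = models.nakagawa_r2(self._fit(1.0, 1.0, 2.0))
        assert m == pytest.approx(0.25) and c == pytest.approx(0.50)

    def test_all_fixed_limit(self):
        m, c = models.nakagawa_r2(self._fit(10.0, 1e-9, 1e-9))
        assert m == pytest.approx(1.0, abs=1e-6) and c >= m

    def test_null_fixed_limit(self):
        m, _ = models.nakagawa_r2(self._fit(0.0, 1.0, 1.0))
        assert m == 0.0

    def test_not_available_for_beta(self):
        f = self._fit(1.0, 1.0, 1.0)
        f.family = "beta"
        assert models.nakagawa_r2(f) == (None, None)


class TestFitLmm:
    def test_reduces_to_ols_without_random_variance(self):
        df, _ = simulate_model_data({"intercept": 2.0, "date": -1.10, "age": 0.5},
                                    {"bird": 0.0}, residual_sd=1.0, n_birds=300,
                                    n_obs_per_bird=5, seed=0, scale_date=True)
        df["date_cov"] = df["date_s"]
        fit = models.fit_lmm(df, "y", ["date_cov", "age"], random=("bird",))
        X, _names = models._design(df, ["date_cov", "age"])
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.terms["estimate"], ols.params, rtol=1e-4)

    def test_recovers_generating_date_effect(self):
        df, _ = simulate_model_data({"intercept": 11.1, "date": -1.10, "age": 0.8},
                                    {"bird": 1.0, "year": 0.5}, residual_sd=2.0,
                                    n_birds=500, n_obs_per_bird=1, n_years=3,
                                    seed=1, scale_date=True)
        df["date_cov"] = df["date_s"]
        fit = models.fit_lmm(df, "y", ["date_cov", "age"])
        assert abs(fit.coef("date_cov") - (-1.10)) < 3 * fit.se("date_cov")
        assert fit.r2_conditional >= fit.r2_marginal
        assert 0 < fit.pvalue("date_cov") <= 1

    def test_row_permutation_invariance(self):
        df, _ = simulate_model_data({"intercept": 1.0, "date": 0.5, "age": 0.2},
                                    {"bird": 0.5, "year": 0.3}, residual_sd=1.0,
                                    n_birds=60, n_obs_per_bird=3, seed=2,
                                    scale_date=True)
        df["date_cov"] = df["date_s"]
        a = models.fit_lmm(df, "y", ["date_cov", "age"])
        b = models.fit_lmm(df.sample(frac=1.0, random_state=9), "y",
                           ["date_cov", "age"])
        np.testing.assert_allclose(a.terms["estimate"], b.terms["estimate"],
                                   atol=1e-6)

    def test_single_level_factor_dropped_with_warning(self, caplog):
        df, _ = simulate_model_data({"intercept": 1.0, "date": 0.5},
                                    {"bird": 0.3}, residual_sd=1.0, n_birds=40,
                                    n_obs_per_bird=2, n_years=1, seed=3,
                                    scale_date=True)
        df["date_cov"] = df["date_s"]
        with caplog.at_level("WARNING"):
            fit = models.fit_lmm(df, "y", ["date_cov"])
        assert "year" not in fit.vcomp
        assert any("year" in r.message for r in caplog.records)


class TestFitBetaGlmm:
    def test_reduction_to_fixed_effect_beta_regression(self):
        """With no random variance and no covariates the Laplace GLMM must
        agree with a plain beta regression (independent implementation)."""
        rng = np.random.default_rng(0)
        y = rng.beta(0.7 * 30, 0.3 * 30, size=300)
        df = pd.DataFrame({"y": y, "bird": [f"b{i}" for i in range(300)],
                           "year": ["y0", "y1"] * 150})
        fit = models.fit_beta_glmm(df, "y", [], random=("year",))
        oracle = BetaModel(y, np.ones((len(y), 1))).fit(disp=False)
        assert fit.coef("Intercept") == pytest.approx(oracle.params[0], abs=1e-3)

    def test_recovers_generating_date_effect(self):
        df, _ = simulate_model_data({"intercept": 1.03, "date": 0.15, "age": -0.25},
                                    {"bird": 0.15, "year": 0.1}, family="beta",
                                    beta_precision=40.0, n_birds=75,
                                    n_obs_per_bird=2, seed=4, scale_date=True)
        df["date_cov"] = df["date_s"]
        fit = models.fit_beta_glmm(df, "y", ["date_cov", "age"])
        assert abs(fit.coef("date_cov") - 0.15) < 3 * fit.se("date_cov")
        assert fit.r2_marginal is None  # not defined for this family

    def test_boundary_response_rejected(self):
        df = pd.DataFrame({"y": [0.2, 1.0, 0.5], "bird": list("abc"),
                           "year": ["y0"] * 3})
        with pytest.raises(ValueError, match="clip"):
            models.fit_beta_glmm(df, "y", [])

    def test_shifting_responses_up_raises_intercept(self):
        rng = np.random.default_rng(5)
        y = rng.beta(12.0, 8.0, size=120)
        df = pd.DataFrame({"y": y, "bird": [f"b{i}" for i in range(120)],
                           "year": ["y0", "y1"] * 60})
        lo = models.fit_beta_glmm(df, "y", [])
        df_hi = df.assign(y=0.5 * df["y"] + 0.5 * 0.95)  # pushed toward 1
        hi = models.fit_beta_glmm(df_hi, "y", [])
        assert hi.coef("Intercept") > lo.coef("Intercept")


@pytest.fixture(scope="module")
def battery(cohort, segmented, classified):
    from storkmig import metrics, weather
    ages = dict(zip(cohort["truth"].birds["bird_id"], cohort["truth"].birds["age"]))
    daily = segmented["daily"]
    mig = daily[daily["day_type"] == "migratory"][["bird_id", "date"]]
    days = pd.DatetimeIndex(classified["timestamp"]).tz_localize(None).normalize()
    key = pd.MultiIndex.from_arrays([classified["bird_id"], days])
    sub = classified[key.isin(pd.MultiIndex.from_frame(mig))]
    annotated = weather.annotate_tracks(sub, cohort["grid"])
    summaries = metrics.summarise(cohort["tracks"], segmented["events"],
                                  daily, classified=classified,
                                  annotated=annotated, ages=ages)
    loggers = cohort["accel"].groupby("bird_id")["logger_type"].first()
    summaries["logger_type"] = summaries["bird_id"].map(loggers)
    dm = weather.daily_means(annotated)
    leg3 = summaries[summaries["leg"] == 3][["bird_id", "start_date",
                                             "start_date_julian", "age", "year"]]
    leg3 = leg3.rename(columns={"start_date_julian": "leg3_start_julian",
                                "start_date": "leg3_start"})
    dm = dm.merge(leg3, on="bird_id", how="inner")
    dm = dm[dm["date"] >= dm["leg3_start"]]
    return models.run_model_battery(summaries, dm)


class TestBattery:
    def test_full_model_list_enumerated(self, battery):
        groups = battery.groupby(["model_group", "response", "leg"]).ngroups
        assert groups == 18 + 6 + 9 + 1

    def test_gaussian_fits_satisfy_r2_ordering(self, battery):
        g = battery[(battery["family"] == "gaussian")
                    & battery["r2_marginal"].notna()]
        assert len(g) > 0
        assert (g["r2_conditional"] >= g["r2_marginal"] - 1e-12).all()

    def test_failures_recorded_not_raised(self, cohort, segmented, classified):
        from storkmig import metrics
        summaries = metrics.summarise(cohort["tracks"], segmented["events"],
                                      segmented["daily"], classified=classified)
        summaries["age"] = "juvenile"  # degenerate: no weather, single age
        out = models.run_model_battery(summaries, None)
        assert (out.loc[out["response"] == "mean_blh", "error"] != "").all()
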