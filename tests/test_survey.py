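"""Design-based logistic regression, Rubin pooling, and the GOF test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import surveysel as sv
from surveysel.exceptions import ConfigurationError, DesignError
from surveysel.survey import SurveyDesign, SurveyLogit, gof_design_adjusted, pool_rubin

from conftest import make_dataset


def _logit_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    eta = -0.5 + 0.8 * X[:, 0] - 0.4 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(X, columns=["x1", "x2"]), y


class TestSurveyLogit:
    def test_degenerate_design_equals_ordinary_mle(self):
        """One stratum, one PSU per record, unit weights: pseudo-MLE is the
        textbook MLE, and SEs match the robust sandwich up to n/(n-1)."""
        X, y = _logit_data()
        exog = pd.DataFrame({"const": 1.0, "x1": X["x1"], "x2": X["x2"]})
        fit = SurveyLogit(y, exog).fit()
        oracle = sm.Logit(y, exog).fit(disp=0)
        assert np.abs(fit.params.to_numpy() - oracle.params.to_numpy()).max() < 1e-8
        robust = sm.Logit(y, exog).fit(disp=0, cov_type="HC0")
        n = len(y)
        ratio = fit.bse.to_numpy() / robust.bse.to_numpy()
        assert np.allclose(ratio, np.sqrt(n / (n - 1)), atol=1e-6)

    def test_weight_scale_invariance(self, survey_dataset):
        fit1 = SurveyLogit.from_dataset(survey_dataset, ["x1", "x2"]).fit()
        ds2 = survey_dataset.copy()
        ds2.values["w"] *= 2.0
        fit2 = SurveyLogit.from_dataset(ds2, ["x1", "x2"]).fit()
        assert np.allclose(fit1.params, fit2.params, atol=1e-10)
        assert np.allclose(fit1.bse, fit2.bse, atol=1e-10)

    def test_design_df_is_psus_minus_strata(self, survey_dataset):
        fit = SurveyLogit.from_dataset(survey_dataset, ["x1"]).fit()
        assert fit.design_df == survey_dataset.design_df == 10  # 20 PSUs - 10 strata

    def test_single_psu_stratum_rejected_unless_collapsed(self):
        strata = np.array([0] * 10 + [1] * 10 + [2] * 5)
        psus = np.array([0, 1] * 5 + [0, 1] * 5 + [0] * 5)
        with pytest.raises(DesignError):
            SurveyDesign(strata, psus, np.ones(25))
        with pytest.warns(UserWarning, match="collapsing"):
            d = SurveyDesign(strata, psus, np.ones(25), collapse=True)
        assert d.n_strata == 2

    def test_subpopulation_estimates_domain_coefficients(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        domain = rng.random(n) < 0.5
        beta = np.where(domain, 1.0, -1.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-(beta * x)))).astype(float)
        exog = pd.DataFrame({"const": 1.0, "x": x})
        fit = SurveyLogit(y, exog, subpop=domain).fit()
        oracle = sm.Logit(y[domain], exog[domain]).fit(disp=0)
        assert fit.params["x"] == pytest.approx(oracle.params["x"], abs=1e-8)
        assert fit.n_used == int(domain.sum())

    def test_separation_raises(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        exog = pd.DataFrame({"const": 1.0, "x": np.r_[np.zeros(10), np.ones(10)]})
        with pytest.raises(sv.exceptions.SeparationError):
            SurveyLogit(y, exog).fit()

    def test_ci_coverage_under_stratified_cluster_design(self):
        """95% CI covers the generating coefficient at near-nominal rate."""
        cover = 0
        n_rep = 120
        for seed in range(n_rep):
            cfg = sv.SimulationConfig(n=2000, p=2, betas=[0.5, 0.3],
                                      target_prevalence=None, intercept=-1.5,
                                      n_strata=15, psus_per_stratum=2, seed=seed)
            ds, _ = sv.generate_survey_study(cfg)
            fit = SurveyLogit.from_dataset(ds, ["x1", "x2"]).fit()
            ci = fit.conf_int().loc["x1"]
            cover += ci["low"] <= 0.5 <= ci["high"]
        assert 0.91 <= cover / n_rep <= 0.985


class TestRubinPooling:
    def _fake_fit(self, params, ses, design_df=16):
        idx = pd.Index([f"b{i}" for i in range(len(params))])
        cov = pd.DataFrame(np.diag(np.asarray(ses) ** 2), index=idx, columns=idx)
        return sv.SurveyLogitResults(
            model=None, params=pd.Series(params, index=idx), cov=cov,
            design_df=design_df, n_used=100, usable=np.ones(100, dtype=bool),
            fitted=np.full(100, 0.5),
        )

    def test_closed_form_toy(self):
        fits = [self._fake_fit([1.0], [1.0]), self._fake_fit([3.0], [1.0])]
        pooled = pool_rubin(fits, complete_data_df=16)
        assert pooled.params.iloc[0] == pytest.approx(2.0)
        assert pooled.within.iloc[0] == pytest.approx(1.0)
        assert pooled.between.iloc[0] == pytest.approx(2.0)
        assert pooled.total.iloc[0] == pytest.approx(4.0)

    def test_identical_fits_degenerate(self):
        f = self._fake_fit([0.7, -0.2], [0.3, 0.4])
        pooled = pool_rubin([f, f, f], complete_data_df=16)
        assert np.allclose(pooled.between, 0.0)
        assert np.allclose(pooled.total, pooled.within)
        assert np.allclose(pooled.params, f.params)
        # Barnard-Rubin limit at r -> 0 is nu_obs = (d+1)/(d+3) * d
        assert np.allclose(pooled.df, 17 / 19 * 16, atol=1e-6)

    def test_order_invariance(self):
        fits = [self._fake_fit([v], [0.5 + 0.1 * i]) for i, v in enumerate([1.0, 1.5, 0.7])]
        a = pool_rubin(fits, 16)
        b = pool_rubin(fits[::-1], 16)
        assert np.allclose(a.params, b.params)
        assert np.allclose(a.total, b.total)
        assert np.allclose(a.df, b.df)

    def test_pooled_df_bounded_and_decreasing_in_between_variance(self):
        """df <= complete-data df over a grid of B/W, decreasing as the
        between-imputation share grows (the Barnard-Rubin behaviour)."""
        dfs = []
        for b_over_w in [0.01, 0.1, 1.0, 10.0, 100.0]:
            spread = np.sqrt(b_over_w)
            qs = spread * np.array([-1.2, -0.6, 0.0, 0.6, 1.2])
            fits = [self._fake_fit([q], [1.0]) for q in qs]
            pooled = pool_rubin(fits, complete_data_df=16)
            assert pooled.df.iloc[0] <= 16 + 1e-9
            dfs.append(float(pooled.df.iloc[0]))
        assert all(a > b for a, b in zip(dfs, dfs[1:]))

    def test_mismatched_terms_rejected(self):
        a = self._fake_fit([1.0], [1.0])
        b = self._fake_fit([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ConfigurationError):
            pool_rubin([a, b], 16)

    def test_single_fit_passthrough(self):
        f = self._fake_fit([0.4], [0.2])
        pooled = pool_rubin([f], complete_data_df=16)
        assert pooled.params.iloc[0] == pytest.approx(0.4)
        assert pooled.total.iloc[0] == pytest.approx(0.04)


class TestGof:
    def _design_15_31(self, n=3100, seed=0):
        """15 strata, 31 PSUs (one stratum holds 3), design df 16."""
        rng = np.random.default_rng(seed)
        strata = np.repeat(np.arange(15), n // 15 + 1)[:n]
        psus = np.zeros(n, dtype=int)
        for h in range(15):
            idx = np.where(strata == h)[0]
            k = 3 if h == 0 else 2
            psus[idx] = rng.integers(0, k, size=len(idx))
        X = rng.standard_normal((n, 2))
        eta = -1.2 + 0.7 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return make_dataset(X, y, weights=np.ones(n), strata=strata, psus=psus)

    def test_df_structure_with_ten_groups(self):
        ds = self._design_15_31()
        fit = SurveyLogit.from_dataset(ds, ["x1", "x2"]).fit()
        res = gof_design_adjusted(fit, g=10)
        assert (res.df_num, res.df_den) == (9, 8)

    def test_saturated_two_group_model_fits_perfectly(self):
        """Binary predictor + intercept saturates two probability groups."""
        rng = np.random.default_rng(4)
        n = 400
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]  # balanced, so the
        # weighted-quantile boundary falls exactly between the two p-hat levels
        y = (rng.random(n) < np.where(x > 0, 0.6, 0.2)).astype(float)
        exog = pd.DataFrame({"const": 1.0, "x": x})
        fit = SurveyLogit(y, exog).fit()
        res = gof_design_adjusted(fit, g=2)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_too_many_groups_for_design_rejected(self, survey_dataset):
        fit = SurveyLogit.from_dataset(survey_dataset, ["x1"]).fit()
        with pytest.raises(ConfigurationError):
            gof_design_adjusted(fit, g=50)
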