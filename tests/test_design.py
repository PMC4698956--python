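import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from svyscan.design import (ConvergenceError, SingletonPSUError, SurveyDesign,
                            SurveyLogisticRegression, design_proportion,
                            fit_weighted_logistic, pool_cycle_weights)

from ._oracles import oracle_proportion, oracle_weighted_logit


def _design(df):
    return SurveyDesign.from_frame(df)


class TestSurveyDesign:
    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            SurveyDesign([1, 1], [1, 2], [1.0, 0.0])

    def test_design_df_is_psus_minus_strata(self, design_fixture_12):
        d = _design(design_fixture_12)
        assert d.n_strata == 2 and d.n_psu == 4 and d.design_df == 2

    def test_psu_labels_nested_within_strata(self):
        # PSU label "1" in stratum 1 and stratum 2 are distinct units
        d = SurveyDesign([1, 1, 2, 2], [1, 2, 1, 2], np.ones(4))
        assert d.n_psu == 4

    def test_singleton_stratum_raises_then_centers(self):
        d_err = SurveyDesign([1, 1, 2], [1, 2, 1], np.ones(3))
        with pytest.raises(SingletonPSUError):
            design_proportion([1, 0, 1], d_err)
        d_ok = SurveyDesign([1, 1, 2], [1, 2, 1], np.ones(3), singleton="center")
        est, se = design_proportion([1, 0, 1], d_ok)
        assert est == pytest.approx(2 / 3)
        assert np.isfinite(se)


class TestDesignProportion:
    def test_weighted_mean_single_stratum(self):
        d = SurveyDesign([1, 1, 1, 1], [1, 1, 2, 2], [2.0, 1.0, 1.0, 1.0])
        est, _ = design_proportion([1, 0, 1, 1], d)
        assert est == pytest.approx(0.8)  # (2+1+1)/5

    def test_equal_weights_reduce_to_sample_proportion(self, rng):
        y = (rng.random(40) < 0.4).astype(float)
        d = SurveyDesign(np.repeat([1, 2], 20), np.tile(np.repeat([1, 2], 10), 2),
                         np.full(40, 3.3))
        est, _ = design_proportion(y, d)
        assert est == pytest.approx(y.mean())

    def test_se_matches_bruteforce_linearization(self, design_fixture_12):
        df = design_fixture_12
        est, se = design_proportion(df["y"], _design(df))
        est_o, se_o = oracle_proportion(df["y"].tolist(), df["weight"].tolist(),
                                        df["stratum"].tolist(), df["psu"].tolist())
        assert est == pytest.approx(est_o, abs=1e-12)
        assert se == pytest.approx(se_o, abs=1e-10)

    def test_scale_invariance_of_estimate_and_se(self, design_fixture_12):
        df = design_fixture_12
        base = design_proportion(df["y"], _design(df))
        d5 = _design(df).replace_weights(pool_cycle_weights(df["weight"], 5))
        assert design_proportion(df["y"], d5) == pytest.approx(base, abs=1e-12)


class TestPoolCycleWeights:
    def test_identity_and_division(self):
        w = np.array([2.0, 4.0])
        assert np.array_equal(pool_cycle_weights(w, 1), w)
        assert np.array_equal(pool_cycle_weights(w, 5), w / 5)

    def test_invalid_cycle_count(self):
        with pytest.raises(ValueError):
            pool_cycle_weights([1.0], 0)


class TestSurveyLogistic:
    def test_equal_weights_srs_equals_classical_mle(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.9 * x)))).astype(int)
        fit = SurveyLogisticRegression().fit(x[:, None], y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params_, ref.params, atol=1e-8)

    def test_sandwich_matches_bruteforce_oracle(self, design_fixture_16):
        df = design_fixture_16
        fit = SurveyLogisticRegression().fit(df[["x"]].to_numpy(), df["y"].to_numpy(),
                                             design=_design(df))
        beta_o, cov_o = oracle_weighted_logit(df["y"], df[["x"]], df["weight"],
                                              df["stratum"].tolist(), df["psu"].tolist())
        assert np.allclose(fit.params_, beta_o, atol=1e-7)
        assert np.allclose(fit.cov_params_, cov_o, atol=1e-8)
        assert np.allclose(fit.bse_, np.sqrt(np.diag(cov_o)), atol=1e-8)

    def test_weight_scale_invariance(self, design_fixture_16):
        df = design_fixture_16
        f1 = SurveyLogisticRegression().fit(df[["x"]].to_numpy(), df["y"].to_numpy(),
                                            design=_design(df))
        d2 = _design(df).replace_weights(df["weight"].to_numpy() * 7.3)
        f2 = SurveyLogisticRegression().fit(df[["x"]].to_numpy(), df["y"].to_numpy(),
                                            design=d2)
        assert np.allclose(f1.params_, f2.params_, atol=1e-9)
        assert np.allclose(f1.bse_, f2.bse_, atol=1e-9)
        assert np.allclose(f1.pvalues(), f2.pvalues(), atol=1e-9)

    def test_sandwich_psd_and_summary_consistency(self, design_fixture_16):
        df = design_fixture_16
        fit, summ = fit_weighted_logistic(df["y"].to_numpy(), df[["x"]].to_numpy(),
                                          _design(df), names=["(Intercept)", "x"])
        assert np.linalg.eigvalsh(fit.cov_params_).min() >= -1e-12
        assert np.allclose(summ["or"], np.exp(summ["coef"]))
        assert (summ["or_low"] <= summ["or"]).all() and (summ["or"] <= summ["or_high"]).all()

    def test_ci_uses_t_with_design_df(self, design_fixture_16):
        from scipy.stats import t as t_dist
        df = design_fixture_16
        fit = SurveyLogisticRegression().fit(df[["x"]].to_numpy(), df["y"].to_numpy(),
                                             design=_design(df))
        ci = fit.conf_int(0.95)
        tc = t_dist.ppf(0.975, fit.design_df_)
        assert np.allclose(ci[:, 1] - ci[:, 0], 2 * tc * fit.bse_, atol=1e-12)

    def test_separation_detected(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(int)
        with pytest.raises(ConvergenceError):
            SurveyLogisticRegression().fit(x[:, None], y)

    def test_robust_se_close_to_mle_se_under_srs(self, rng):
        # one PSU per subject, equal weights: linearized SE ~ classical SE
        n = 4000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.7 * x)))).astype(int)
        fit = SurveyLogisticRegression().fit(x[:, None], y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert np.allclose(fit.bse_, ref.bse, rtol=0.05)

    def test_warm_start_reaches_same_optimum(self, design_fixture_16):
        df = design_fixture_16
        cold = SurveyLogisticRegression().fit(df[["x"]].to_numpy(),
                                              df["y"].to_numpy(), design=_design(df))
        warm = SurveyLogisticRegression().fit(
            df[["x"]].to_numpy(), df["y"].to_numpy(), design=_design(df),
            start_params=cold.params_ + 0.3)
        assert np.allclose(cold.params_, warm.params_, atol=1e-9)

    def test_nonbinary_response_rejected(self):
        with pytest.raises(ValueError):
            SurveyLogisticRegression().fit(np.ones((3, 1)), [0, 1, 2])
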