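import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svyscan as sv
from svyscan.scan import (MODEL_COVARIATE_ORDER, bonferroni, default_model_sequence,
                          encode_covariates, molar_sum_dnop)


class TestBonferroni:
    @pytest.mark.parametrize("p,expected", [
        (0.004, 0.048),      # the strongest univariate signal
        (0.053, 0.636),      # the runner-up
        (0.285, 1.0),        # capped
        (1 / 12, 1.0),       # boundary: exactly m*p = 1
    ])
    def test_printed_examples_m12(self, p, expected):
        assert bonferroni(p, m=12) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50))
    def test_property_monotone_capped_and_above_nominal(self, p1, p2, m):
        c1, c2 = bonferroni(p1, m), bonferroni(p2, m)
        assert 0 <= c1 <= 1
        assert c1 >= p1                      # corrected never below nominal
        if p1 <= p2:
            assert c1 <= c2                  # monotone

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5)
        with pytest.raises(ValueError):
            bonferroni(0.5, m=0)


class TestMolarSum:
    def test_one_molar_mass_of_each_gives_one_micromolar(self):
        # MOP C16H22O4 = 278.34 g/mol; MCPP C12H12O6 = 252.22 g/mol
        assert molar_sum_dnop(278.34, 0.0) == pytest.approx(1.0)
        assert molar_sum_dnop(0.0, 252.22) == pytest.approx(1.0)
        assert molar_sum_dnop(0.0, 0.0) == 0.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            molar_sum_dnop(-1.0, 0.0)


class TestCovariateCoding:
    def test_threshold_codings(self):
        df = pd.DataFrame({
            "age": [45.0], "male": [1], "ethnicity": ["mexican_american"],
            "married": [1], "education": [3], "pir": [np.nan], "mets": [7.0],
            "hba1c": [7.0], "total_chol": [250.0], "hdl": [35.0],
            "triglycerides": [160.0], "hypertension": [np.nan],
            "duration_dm": [15.0], "kcal": [1500.0], "bmi": [32.0],
        })
        coded = encode_covariates(df).iloc[0]
        assert coded["obesity_cat"] == 2          # BMI >= 30
        assert coded["htn_cat"] == 0              # unknown -> 0
        assert coded["activity"] == 2             # > 6 METS = active
        assert coded["hba1c_cat"] == 2 and coded["total_chol_cat"] == 2
        assert coded["low_hdl_cat"] == 2          # male with HDL < 40
        assert coded["trig_cat"] == 2
        assert coded["duration_dm_cat"] == 4      # >= 14 years
        assert coded["kcal_q"] == 1               # second quartile band
        assert coded["pir"] == 0.0                # missing -> 0
        assert coded["hispanic"] == 1

    def test_female_hdl_threshold_and_missing_to_zero(self):
        df = pd.DataFrame({
            "age": [60.0], "male": [0], "ethnicity": ["nh_white"], "married": [0],
            "education": [np.nan], "pir": [2.5], "mets": [np.nan], "hba1c": [6.0],
            "total_chol": [np.nan], "hdl": [45.0], "triglycerides": [np.nan],
            "hypertension": [1.0], "duration_dm": [np.nan], "kcal": [np.nan],
            "bmi": [np.nan],
        })
        coded = encode_covariates(df).iloc[0]
        assert coded["low_hdl_cat"] == 2          # female with HDL < 50
        assert coded["hba1c_cat"] == 1
        assert coded["htn_cat"] == 2
        for c in ["education", "activity", "total_chol_cat", "trig_cat",
                  "duration_dm_cat", "kcal_q", "obesity_cat"]:
            assert coded[c] == 0                  # missing always codes to 0

    def test_every_confounder_coding_handles_missing(self, analysis_frame):
        coded = analysis_frame[MODEL_COVARIATE_ORDER]
        assert coded.notna().all().all()


class TestUnivariateScan:
    def test_scan_shape_and_correction(self, analysis_frame, design):
        res = sv.univariate_scan(analysis_frame, design)
        assert len(res) == 12
        valid = res["p"].notna()
        assert np.allclose(res.loc[valid, "p_bonferroni"],
                           np.minimum(1, 12 * res.loc[valid, "p"]))
        assert (res.loc[valid, "p_bonferroni"] >= res.loc[valid, "p"]).all()

    def test_univariate_or_invariant_to_other_columns(self, analysis_frame, design, rng):
        res = sv.univariate_scan(analysis_frame, design)
        shuffled = analysis_frame.copy()
        others = [f"z_{m}" for m in sv.METABOLITES if m != "MOP"]
        shuffled[others] = shuffled[others].sample(frac=1.0, random_state=3).to_numpy()
        res2 = sv.univariate_scan(shuffled, design)
        assert res.loc["z_MOP", "odds_ratio"] == pytest.approx(
            res2.loc["z_MOP", "odds_ratio"], abs=1e-12)

    def test_m_fixed_even_with_failures(self, analysis_frame, design):
        broken = analysis_frame.copy()
        broken["z_MBP"] = 0.0   # constant predictor cannot be fit
        res = sv.univariate_scan(broken, design)
        assert res.loc["z_MBP", "error"] != ""
        assert np.isnan(res.loc["z_MBP", "p_bonferroni"])
        ok = res.drop("z_MBP")
        assert np.allclose(ok["p_bonferroni"].dropna(),
                           np.minimum(1, 12 * ok["p"].dropna()))


class TestNestedModels:
    def test_sequence_is_cumulative_table_order(self):
        seq = default_model_sequence("z_MOP")
        assert len(seq) == 16
        assert len(seq[0]) == 12 and seq[0][0] == "z_MOP"
        for a, b in zip(seq, seq[1:]):
            assert b[:-1] == a                   # each model adds one term
        assert [m[-1] for m in seq[1:]] == MODEL_COVARIATE_ORDER

    def test_reports_exposure_row_for_each_model(self, analysis_frame, design):
        nested = sv.nested_models(analysis_frame, design)
        assert list(nested.index) == list(range(1, 17))
        assert (nested["error"] == "").all()
        assert np.allclose(nested["odds_ratio"], np.exp(nested["coef"]))

    def test_collinear_model_flagged_but_scan_continues(self, analysis_frame, design):
        seq = [["z_MOP", "z_MBP"], ["z_MOP", "z_MBP", "dup"], ["z_MOP"]]
        df = analysis_frame.copy()
        df["dup"] = df["z_MBP"]                 # exact collinearity
        nested = sv.nested_models(df, design, model_sequence=seq)
        assert nested.loc[2, "error"] != ""
        assert nested.loc[1, "error"] == "" and nested.loc[3, "error"] == ""

    def test_irrelevant_covariate_barely_moves_estimate(self, rng):
        # at large n a covariate independent of outcome and exposure
        # changes the exposure OR by well under 5%
        n = 8000
        x = rng.normal(size=n)
        junk = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.5 * x)))).astype(int)
        df = pd.DataFrame({"z_MOP": x, "junk": junk, "y": y})
        d = sv.SurveyDesign(np.zeros(n, int), np.arange(n), np.ones(n))
        nested = sv.nested_models(df, d, outcome="y",
                                  model_sequence=[["z_MOP"], ["z_MOP", "junk"]])
        assert nested.loc[2, "odds_ratio"] == pytest.approx(
            nested.loc[1, "odds_ratio"], rel=0.05)
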