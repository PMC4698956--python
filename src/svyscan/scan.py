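"""Association scanning: covariate coding, univariate scan, nested models.

The analysis regresses a binary self-reported outcome on each of 12
inverse-normalised urinary phthalate metabolites (one design-based
logistic model per metabolite, Bonferroni-corrected over the 12 tests),
then probes the robustness of the leading signal through a fixed
sequence of 16 cumulative multivariable models that add the other 11
metabolites and then demographic/clinical covariates one block at a
time, always retaining everything added earlier.

Covariates are coded to small integers with missing mapped to 0, so
every subject enters every model (no listwise deletion); the coding
tables live in :data:`COVARIATE_CODING`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ConvergenceError, SingletonPSUError, SurveyDesign, SurveyLogisticRegression

__all__ = [
    "METABOLITES",
    "MOLAR_MASS",
    "bonferroni",
    "encode_covariates",
    "univariate_scan",
    "nested_models",
    "default_model_sequence",
    "molar_sum_dnop",
]

#: the 12 fully measured urinary phthalate metabolites, in report order
METABOLITES = [
    "MBP", "MCP", "MEP", "MEHP", "MNP", "MOP",
    "MBzP", "MNM", "MCPP", "MEHHP", "MEOHP", "MiBP",
]

#: molar masses (g/mol) from the metabolites' molecular formulas
#: MOP  = mono-n-octyl phthalate,          C16H22O4
#: MCPP = mono-(3-carboxypropyl) phthalate, C12H12O6
MOLAR_MASS = {"MOP": 278.34, "MCPP": 252.22}


def bonferroni(pvalues, m: int = 12):
    """Bonferroni correction: ``min(1, m * p)``, elementwise.

    ``m`` is the number of tests in the family and is fixed a priori
    (default 12, the metabolite panel size) regardless of how many fits
    succeeded.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# Covariate coding
# ---------------------------------------------------------------------------

def _code_education(v):
    # 1..5 from <9th grade to college graduate; refused/unknown -> 0
    return 0 if pd.isna(v) or v < 1 or v > 5 else int(v)


def _code_duration_dm(years):
    if pd.isna(years):
        return 0
    if years >= 14:
        return 4
    if years >= 8:
        return 3
    if years >= 3:
        return 2
    return 1


def _code_kcal_quartile(kcal, cuts=(1200.5, 1648.5, 2191.0)):
    if pd.isna(kcal):
        return 0
    return int(np.searchsorted(cuts, kcal, side="right"))


def _code_low_hdl(hdl, male):
    if pd.isna(hdl) or pd.isna(male):
        return 0
    return 2 if hdl < (40 if male else 50) else 1


#: raw-column -> coded-column specification mirroring the study's coding
#: tables. Each entry is (coded name, function of the cohort frame).
COVARIATE_CODING = {
    "age": ("age", lambda df: df["age"].fillna(0.0)),
    "sex": ("male", lambda df: df["male"].fillna(0).astype(int)),
    "ethnicity": (
        "hispanic",  # Mexican American / other Hispanic -> 1, else 0
        lambda df: df["ethnicity"].isin(["mexican_american", "hispanic"]).astype(int),
    ),
    "married": ("married", lambda df: df["married"].fillna(0).astype(int)),
    "education": ("education", lambda df: df["education"].map(_code_education)),
    "pir": ("pir", lambda df: df["pir"].fillna(0.0)),  # poverty income ratio, raw or 0
    "activity": (
        "activity",  # >6 METS active=2; 3-6 insufficient=1; <3 or unknown=0
        lambda df: df["mets"].map(
            lambda m: 0 if pd.isna(m) or m < 3 else (1 if m <= 6 else 2)
        ),
    ),
    "hba1c": (
        "hba1c_cat",  # >=6.5%=2, <6.5%=1, unknown=0
        lambda df: df["hba1c"].map(lambda v: 0 if pd.isna(v) else (2 if v >= 6.5 else 1)),
    ),
    "total_chol": (
        "total_chol_cat",  # >=240 mg/dL=2, <240=1, unknown=0
        lambda df: df["total_chol"].map(lambda v: 0 if pd.isna(v) else (2 if v >= 240 else 1)),
    ),
    "hdl": (
        "low_hdl_cat",  # sex-specific low HDL=2, normal=1, unknown=0
        lambda df: [
            _code_low_hdl(h, m) for h, m in zip(df["hdl"], df["male"])
        ],
    ),
    "triglycerides": (
        "trig_cat",  # >=150 mg/dL=2, <150=1, unknown=0
        lambda df: df["triglycerides"].map(
            lambda v: 0 if pd.isna(v) else (2 if v >= 150 else 1)
        ),
    ),
    "hypertension": (
        "htn_cat",  # yes=2, no=1, unknown=0
        lambda df: df["hypertension"].map(
            lambda v: 0 if pd.isna(v) else (2 if v else 1)
        ),
    ),
    "duration_dm": ("duration_dm_cat", lambda df: df["duration_dm"].map(_code_duration_dm)),
    "kcal": ("kcal_q", lambda df: df["kcal"].map(_code_kcal_quartile)),
    "obesity": (
        "obesity_cat",  # BMI>=30=2, <30=1, not measured=0
        lambda df: df["bmi"].map(lambda v: 0 if pd.isna(v) else (2 if v >= 30 else 1)),
    ),
}


def encode_covariates(cohort: pd.DataFrame, coding: dict | None = None) -> pd.DataFrame:
    """Code raw covariates to the analysis integers (missing -> 0).

    Applies every entry of ``coding`` (default :data:`COVARIATE_CODING`)
    whose raw columns are present; raises if a listed raw column is
    absent. Returns a DataFrame of coded columns indexed like ``cohort``.
    """
    coding = COVARIATE_CODING if coding is None else coding
    out = {}
    for raw, (name, fn) in coding.items():
        try:
            out[name] = np.asarray(fn(cohort), dtype=float)
        except KeyError as exc:
            raise KeyError(f"covariate {raw!r} needs raw column {exc.args[0]!r}") from exc
    return pd.DataFrame(out, index=cohort.index)


#: coded covariate columns in the order the cumulative models add them
MODEL_COVARIATE_ORDER = [
    "age", "male", "hispanic", "married", "education", "pir", "activity",
    "hba1c_cat", "total_chol_cat", "low_hdl_cat", "trig_cat", "htn_cat",
    "duration_dm_cat", "kcal_q", "obesity_cat",
]


def default_model_sequence(exposure: str = "z_MOP") -> list[list[str]]:
    """The 16 cumulative model specifications for the nested analysis.

    Model 1 is the exposure plus the other 11 metabolites; models 2-16
    each add one coded covariate block, retaining everything before it.
    """
    other = [f"z_{m}" for m in METABOLITES if f"z_{m}" != exposure]
    seq = [[exposure] + other]
    for cov in MODEL_COVARIATE_ORDER:
        seq.append(seq[-1] + [cov])
    return seq


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def univariate_scan(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    outcome: str = "selfreport_outcome",
    exposures: list[str] | None = None,
    m: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """One design-based logistic model per exposure, Bonferroni-corrected.

    Returns a per-exposure table of coefficient, SE, OR, CI bounds,
    nominal p and corrected p (``min(1, m*p)``, m defaulting to the
    number of exposures scanned). Failed fits are flagged in an
    ``error`` column and get NaN estimates; the scan continues.
    """
    if exposures is None:
        exposures = [f"z_{met}" for met in METABOLITES]
    if m is None:
        m = len(exposures)
    y = cohort[outcome].to_numpy(dtype=float)
    rows = []
    for col in exposures:
        row = {"exposure": col}
        try:
            fit = SurveyLogisticRegression().fit(cohort[[col]].to_numpy(), y, design=design)
            sf = fit.summary_frame(level=level).iloc[1]
            row.update(coef=sf["coef"], se=sf["se"], odds_ratio=sf["or"],
                       or_low=sf["or_low"], or_high=sf["or_high"], p=sf["p"], error="")
        except (ConvergenceError, SingletonPSUError, np.linalg.LinAlgError) as exc:
            row.update(coef=np.nan, se=np.nan, odds_ratio=np.nan,
                       or_low=np.nan, or_high=np.nan, p=np.nan, error=str(exc))
        rows.append(row)
    res = pd.DataFrame(rows).set_index("exposure")
    res["p_bonferroni"] = bonferroni(res["p"].fillna(1.0), m=m)
    res.loc[res["p"].isna(), "p_bonferroni"] = np.nan
    return res


def nested_models(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    outcome: str = "selfreport_outcome",
    exposure: str = "z_MOP",
    model_sequence: list[list[str]] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Cumulative multivariable models; report the exposure term of each.

    ``model_sequence`` is a list of column lists, each of which must
    contain ``exposure``. Collinear or otherwise unfittable models are
    flagged and skipped (NaN row), later models still run.
    """
    if model_sequence is None:
        model_sequence = default_model_sequence(exposure)
    y = cohort[outcome].to_numpy(dtype=float)
    rows = []
    for i, cols in enumerate(model_sequence, start=1):
        if exposure not in cols:
            raise ValueError(f"model {i} does not include the exposure {exposure!r}")
        row = {"model": i, "n_covariates": len(cols), "terms": "+".join(cols)}
        try:
            fit = SurveyLogisticRegression().fit(cohort[cols].to_numpy(), y, design=design)
            sf = fit.summary_frame(level=level, names=["(Intercept)"] + cols)
            sx = sf.loc[exposure]
            row.update(coef=sx["coef"], se=sx["se"], odds_ratio=sx["or"],
                       or_low=sx["or_low"], or_high=sx["or_high"], p=sx["p"], error="")
        except (ConvergenceError, SingletonPSUError, np.linalg.LinAlgError) as exc:
            row.update(coef=np.nan, se=np.nan, odds_ratio=np.nan,
                       or_low=np.nan, or_high=np.nan, p=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def molar_sum_dnop(mop_conc, mcpp_conc):
    """Molar sum of the two di-n-octyl phthalate (DnOP) metabolites.

    Converts mass concentrations (ng/mL) of MOP and MCPP to molarity and
    adds them; ng/mL divided by g/mol is nmol/mL, i.e. µmol/L. The sum
    then goes through the standard transform chain like any exposure.
    """
    mop = np.asarray(mop_conc, dtype=float)
    mcpp = np.asarray(mcpp_conc, dtype=float)
    if np.any(mop < 0) or np.any(mcpp < 0):
        raise ValueError("concentrations must be nonnegative")
    return mop / MOLAR_MASS["MOP"] + mcpp / MOLAR_MASS["MCPP"]
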