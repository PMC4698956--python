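"""Synthetic NHANES-like cohort generator with known ground truth.

Emulates the structure of a pooled national health-survey extract of
adults with type-2 diabetes: a stratified design with two PSUs per
stratum and unequal log-normal sampling weights, twelve correlated
log-normal urinary phthalate metabolite concentrations censored at
per-metabolite detection limits, urinary creatinine, the demographic
and clinical covariates of the analysis coding tables, a latent true
eye-complication outcome drawn from a logistic model on the
inverse-normalised exposures, a self-reported outcome derived from the
truth with specified error rates, and a 4-level imaging grade available
only in a substudy.

Every stage of the analysis pipeline can therefore be tested against
known truth: true log odds ratios, true misreporting rates, and the
uncensored concentrations are all retained (columns prefixed
``true_``/``raw_``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .scan import METABOLITES
from .transform import dilution_correct, inverse_normal, substitute_lod

__all__ = [
    "LogNormalSpec",
    "GeneratorConfig",
    "default_correlation",
    "generate_cohort",
    "apply_inclusion_criteria",
    "inject_misclassification",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution spec: exp(N(mu, sigma^2)), strictly positive."""

    mu: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


def default_correlation(n: int = 12) -> np.ndarray:
    """Plausible metabolite log-concentration correlation structure.

    A mild common background (0.2) with two tighter blocks: the three
    DEHP oxidation products (MEHP, MEHHP, MEOHP; 0.8 among the
    secondary metabolites) and the two DnOP derivatives (MOP, MCPP;
    0.4). Projected to the nearest PSD correlation matrix if needed.
    """
    corr = np.full((n, n), 0.2)
    np.fill_diagonal(corr, 1.0)
    idx = {m: i for i, m in enumerate(METABOLITES[:n])}
    def _set(a, b, r):
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    _set("MEHP", "MEHHP", 0.6)
    _set("MEHP", "MEOHP", 0.6)
    _set("MEHHP", "MEOHP", 0.8)
    _set("MOP", "MCPP", 0.4)
    _set("MBP", "MiBP", 0.5)
    return nearest_psd_correlation(corr)


def nearest_psd_correlation(corr: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    if vals.min() >= 0:
        return corr
    m = (vecs * np.clip(vals, eps, None)) @ vecs.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


# log-scale geometric means (log ng/mL), loosely matched to the reported
# arithmetic means under unit log-SD (geometric mean ~ mean / exp(sd^2/2))
_DEFAULT_LOG_MEANS = {
    "MBP": 3.2, "MCP": -1.4, "MEP": 5.0, "MEHP": 1.2, "MNP": -0.1,
    "MOP": -0.4, "MBzP": 2.0, "MNM": 0.8, "MCPP": 1.1, "MEHHP": 3.2,
    "MEOHP": 2.7, "MiBP": 1.7,
}
# per-metabolite detection limits (ng/mL); MOP's is the assay's 0.84
_DEFAULT_LODS = {
    "MBP": 0.4, "MCP": 0.2, "MEP": 0.5, "MEHP": 0.6, "MNP": 0.8,
    "MOP": 0.84, "MBzP": 0.3, "MNM": 1.0, "MCPP": 0.2, "MEHHP": 0.3,
    "MEOHP": 0.3, "MiBP": 0.3,
}


def _default_true_log_or() -> dict[str, float]:
    # one genuinely associated exposure (MOP, OR 1.39 per SD), others null
    return {"MOP": float(np.log(1.39))}


@dataclass
class GeneratorConfig:
    """Data-generating assumptions for the synthetic cohort.

    Defaults mirror the analysed study population: ~1,000 adults with
    diabetes from a stratified two-PSU-per-stratum design, 12 correlated
    log-normal exposures with LOD censoring, ~14% outcome prevalence,
    imaging substudy covering ~28% of subjects, and self-report error
    rates of 11.2% (false positive) and 4.92% (false negative).
    """

    n_subjects: int = 1000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_law: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(9.0, 0.7))
    metabolite_names: list[str] = field(default_factory=lambda: list(METABOLITES))
    log_conc_means: np.ndarray | None = None
    log_conc_sds: np.ndarray | None = None
    conc_correlation: np.ndarray | None = None
    lods: dict[str, float] | None = None
    creatinine_law: LogNormalSpec = field(default_factory=lambda: LogNormalSpec(4.6, 0.6))
    true_log_or: dict[str, float] = field(default_factory=_default_true_log_or)
    covariate_log_or: dict[str, float] = field(default_factory=dict)
    intercept: float = -1.82        # ~14% baseline outcome prevalence
    substudy_fraction: float = 0.284
    selfreport_fp_rate: float = 0.112
    selfreport_fn_rate: float = 0.0492
    grade_probs_case: tuple = (0.25, 0.60, 0.15)     # mild, modsev, PR given true=1
    grade_probs_control: tuple = (0.90, 0.10)        # none, mild given true=0
    seed: int = 0

    def resolve(self) -> "GeneratorConfig":
        """Fill derived defaults and validate invariants."""
        k = len(self.metabolite_names)
        cfg = replace(self)
        if cfg.log_conc_means is None:
            cfg.log_conc_means = np.array(
                [_DEFAULT_LOG_MEANS.get(m, 1.0) for m in cfg.metabolite_names])
        if cfg.log_conc_sds is None:
            cfg.log_conc_sds = np.ones(k)
        if cfg.conc_correlation is None:
            cfg.conc_correlation = default_correlation(k)
        if cfg.lods is None:
            cfg.lods = {m: _DEFAULT_LODS.get(m, 0.5) for m in cfg.metabolite_names}
        cfg.log_conc_means = np.asarray(cfg.log_conc_means, dtype=float)
        cfg.log_conc_sds = np.asarray(cfg.log_conc_sds, dtype=float)
        corr = np.asarray(cfg.conc_correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError("conc_correlation must be square, one row per metabolite")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("conc_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("conc_correlation is not positive semi-definite")
        if any(l <= 0 for l in cfg.lods.values()):
            raise ValueError("all LODs must be positive")
        for r in (cfg.selfreport_fp_rate, cfg.selfreport_fn_rate, cfg.substudy_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates and fractions must lie in [0, 1]")
        if cfg.psus_per_stratum < 2:
            raise ValueError("need >= 2 PSUs per stratum for design variance")
        if cfg.n_subjects < cfg.n_strata * cfg.psus_per_stratum:
            raise ValueError("n_subjects too small to fill every stratum/PSU cell")
        return cfg


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def inject_misclassification(outcome, fp_rate: float, fn_rate: float, seed=None):
    """Randomly reshuffle observed cases and controls at fixed rates.

    Each observed case (1) is independently flipped to control with
    probability ``fp_rate`` (the share of observed cases believed
    spurious) and each observed control (0) to case with probability
    ``fn_rate`` (the share of observed controls hiding true cases).
    ``seed`` may be an int or a Generator; the flip pattern is
    deterministic given it.
    """
    if not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise ValueError("misclassification rates must lie in [0, 1]")
    y = np.asarray(outcome, dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(len(y))
    flip = np.where(y == 1, u < fp_rate, u < fn_rate)
    return np.where(flip, 1 - y, y)


def _gen_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Raw covariates with marginals close to the study table (incl. missingness)."""
    def miss(x, p):
        x = np.asarray(x, dtype=float)
        x[rng.random(n) < p] = np.nan
        return x

    age = np.clip(rng.normal(60, 13, n), 20, 85).round(0)
    duration = np.where(rng.random(n) < 0.17, np.nan,
                        np.clip(rng.gamma(2.0, 5.0, n), 0, 50).round(0))
    df = pd.DataFrame({
        "age": age,
        "male": rng.random(n) < 0.49,
        "ethnicity": rng.choice(
            ["mexican_american", "hispanic", "nh_white", "nh_black", "other"],
            size=n, p=[0.21, 0.07, 0.41, 0.27, 0.04]),
        "married": rng.random(n) < 0.55,
        "education": rng.choice([1, 2, 3, 4, 5], size=n, p=[0.22, 0.19, 0.22, 0.25, 0.12]),
        "pir": miss(np.clip(rng.lognormal(0.8, 0.6, n), 0, 5).round(2), 0.07),
        "mets": np.clip(rng.gamma(1.5, 3.0, n), 0, 40).round(1),
        "hba1c": miss(np.clip(rng.normal(7.2, 1.6, n), 4.5, 14).round(1), 0.10),
        "total_chol": miss(rng.normal(195, 40, n).round(0), 0.05),
        "hdl": miss(np.clip(rng.normal(48, 14, n), 15, 120).round(0), 0.05),
        "triglycerides": miss(np.clip(rng.lognormal(5.0, 0.5, n), 30, 1500).round(0), 0.20),
        "hypertension": miss((rng.random(n) < 0.30).astype(float), 0.05),
        "duration_dm": duration,
        "kcal": miss(np.clip(rng.lognormal(7.45, 0.45, n), 300, 8000).round(0), 0.02),
        "bmi": miss(np.clip(rng.normal(31.5, 6.5, n), 15, 70).round(1), 0.03),
    })
    df["male"] = df["male"].astype(int)
    df["married"] = df["married"].astype(int)
    return df


def _gen_eligibility(rng: np.random.Generator, n: int, age: np.ndarray,
                     duration: np.ndarray, hba1c: np.ndarray) -> pd.DataFrame:
    """Diabetes-screening answers; most subjects qualify as adult diabetics."""
    choice = rng.choice(["yes", "no", "missing"], size=n, p=[0.84, 0.13, 0.03])
    insulin = np.where(
        (choice == "yes") & (rng.random(n) < 0.30), "yes",
        rng.choice(["no", "missing"], size=n, p=[0.97, 0.03]))
    pills = np.where(
        (choice == "yes") & (rng.random(n) < 0.55), "yes",
        rng.choice(["no", "missing"], size=n, p=[0.97, 0.03]))
    # diagnosed subjects get an age at diagnosis; a small tail below 20
    # exercises the type-1-suspect exclusion; undiagnosed have none
    dur = np.where(np.isnan(duration), 8.0, duration)
    age_dx = np.where(choice == "yes", np.maximum(age - dur - rng.integers(0, 3, n), 5), np.nan)
    return pd.DataFrame({
        "dm_selfreport": choice, "insulin": insulin, "pills": pills,
        "age_screening": age, "age_diagnosis": age_dx, "hba1c_screen": hba1c,
    })


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``.

    One master seed feeds named substreams (design, exposures,
    covariates, outcome, self-report, substudy, eligibility), so each
    component is individually reproducible when upstream configuration
    is unchanged.
    """
    cfg = (config or GeneratorConfig()).resolve()
    n, k = cfg.n_subjects, len(cfg.metabolite_names)
    rngs = _substreams(cfg.seed, [
        "design", "exposure", "creatinine", "covariates", "outcome",
        "selfreport", "substudy", "eligibility",
    ])

    # --- survey design: round-robin fill so every stratum/PSU cell is nonempty
    cells = cfg.n_strata * cfg.psus_per_stratum
    cell_idx = np.arange(n) % cells
    stratum = cell_idx // cfg.psus_per_stratum + 1
    psu = cell_idx % cfg.psus_per_stratum + 1
    weights = cfg.weight_law.sample(rngs["design"], n)

    # --- correlated log-normal exposures, censored at the LOD
    cov = np.outer(cfg.log_conc_sds, cfg.log_conc_sds) * cfg.conc_correlation
    logc = rngs["exposure"].multivariate_normal(cfg.log_conc_means, cov, size=n,
                                                method="cholesky")
    raw_conc = np.exp(logc)
    lod_vec = np.array([cfg.lods[m] for m in cfg.metabolite_names])
    below = raw_conc < lod_vec
    conc = np.where(below, lod_vec / 2.0, raw_conc)

    creatinine = cfg.creatinine_law.sample(rngs["creatinine"], n)
    covars = _gen_covariates(rngs["covariates"], n)
    elig = _gen_eligibility(rngs["eligibility"], n, covars["age"].to_numpy(),
                            covars["duration_dm"].to_numpy(), covars["hba1c"].to_numpy())

    # --- true outcome from the logistic model on transformed exposures
    beta = np.array([cfg.true_log_or.get(m, 0.0) for m in cfg.metabolite_names])
    z = np.column_stack([
        inverse_normal(dilution_correct(conc[:, j], creatinine))
        for j in range(k)
    ])
    eta = cfg.intercept + z @ beta
    if cfg.covariate_log_or:
        from .scan import encode_covariates
        coded = encode_covariates(covars)
        for name, b in cfg.covariate_log_or.items():
            eta = eta + b * coded[name].to_numpy()
    true_outcome = (rngs["outcome"].random(n) < expit(eta)).astype(int)

    # --- self-report: truth-conditional reporting errors
    u = rngs["selfreport"].random(n)
    selfreport = np.where(
        true_outcome == 1,
        (u >= cfg.selfreport_fn_rate).astype(int),   # missed with prob fn
        (u < cfg.selfreport_fp_rate).astype(int),    # spurious with prob fp
    )

    # --- imaging substudy with severity grades
    in_substudy = rngs["substudy"].random(n) < cfg.substudy_fraction
    g = rngs["substudy"]
    grade = np.full(n, "missing", dtype=object)
    case = in_substudy & (true_outcome == 1)
    ctrl = in_substudy & (true_outcome == 0)
    grade[case] = g.choice(["mild_npr", "modsev_npr", "pr"], size=int(case.sum()),
                           p=np.asarray(cfg.grade_probs_case) / np.sum(cfg.grade_probs_case))
    grade[ctrl] = g.choice(["none", "mild_npr"], size=int(ctrl.sum()),
                           p=np.asarray(cfg.grade_probs_control) / np.sum(cfg.grade_probs_control))

    out = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "stratum": stratum,
        "psu": psu,
        "weight": weights,
        "creatinine": creatinine,
    })
    for j, m in enumerate(cfg.metabolite_names):
        out[m] = conc[:, j]
        out[f"{m}_below_lod"] = below[:, j]
        out[f"raw_{m}"] = raw_conc[:, j]
    out = pd.concat([out, covars, elig], axis=1)
    out["true_outcome"] = true_outcome
    out["selfreport_outcome"] = selfreport
    out["in_substudy"] = in_substudy
    out["imaging_grade"] = grade
    return out


def apply_inclusion_criteria(cohort: pd.DataFrame, return_flow: bool = False):
    """Select adult type-2 diabetes cases, logging the selection flow.

    A subject qualifies as having diabetes by answering yes to any of
    the three screening questions (told has diabetes / taking insulin /
    taking diabetic pills) or, failing that, by a glycated-hemoglobin
    value of at least 6.5% (undiagnosed diabetes). Subjects whose
    self-report answer is missing/refused and who meet no other
    criterion are dropped. Type-2 likelihood then requires age at
    screening >= 20 and, where known, age at diagnosis >= 20.

    Returns the filtered frame, plus an ordered stage->count dict when
    ``return_flow`` is true.
    """
    df = cohort
    flow = {"input": len(df)}
    yes = lambda col: df[col].astype(str).str.lower().eq("yes")
    reported = yes("dm_selfreport") | yes("insulin") | yes("pills")
    undiagnosed = ~reported & (df["hba1c_screen"] >= 6.5)
    diabetic = reported | undiagnosed
    flow["self-reported or treated diabetes"] = int(reported.sum())
    flow["added undiagnosed (HbA1c >= 6.5%)"] = int(undiagnosed.sum())
    flow["diabetes (any criterion)"] = int(diabetic.sum())
    df = df[diabetic]
    adult = df["age_screening"] >= 20
    dx_ok = df["age_diagnosis"].isna() | (df["age_diagnosis"] >= 20)
    df = df[adult & dx_ok]
    flow["adult-onset (both ages >= 20 y)"] = len(df)
    df = df.reset_index(drop=True)
    return (df, flow) if return_flow else df
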