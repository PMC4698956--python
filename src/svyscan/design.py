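"""Design-based estimation for stratified multi-stage surveys.

Implements the two estimators the analysis needs under a stratified,
clustered, unequally weighted design (strata / primary sampling units /
sampling weights, as released with NHANES-style public files):

* Horvitz–Thompson ratio estimates of means and proportions with
  Taylor-linearized standard errors, and
* pseudo-maximum-likelihood logistic regression with the stratified
  between-PSU sandwich (linearized) covariance.

Variance estimation follows the "with replacement" first-stage
approximation: within each stratum h with ``n_h`` sampled PSUs, the PSU
totals of the linearized scores ``z_hj`` contribute

    V = sum_h n_h / (n_h - 1) * sum_j (z_hj - zbar_h)(z_hj - zbar_h)'

and for regression the covariance is the sandwich B V B with
B the inverse of the weighted-information (bread) matrix. Confidence
intervals and p-values use a t reference with design degrees of freedom
(#PSUs - #strata), the convention of the major survey packages. No
finite-population correction and no replicate-weight methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

__all__ = [
    "SurveyDesign",
    "design_proportion",
    "design_mean",
    "SurveyLogisticRegression",
    "fit_weighted_logistic",
    "pool_cycle_weights",
    "ConvergenceError",
    "SingletonPSUError",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge (or the fit diverged / separated)."""


class SingletonPSUError(ValueError):
    """A stratum contains a single PSU and no centering override was requested."""


@dataclass
class SurveyDesign:
    """Per-subject survey design variables.

    Parameters
    ----------
    strata : array-like
        Stratum label per subject.
    psu : array-like
        Primary-sampling-unit label per subject (nested within stratum;
        labels are combined with the stratum label internally so reused
        PSU names across strata are safe).
    weights : array-like of float
        Positive sampling weights.
    singleton : {"error", "center"}
        How to handle strata with a single PSU: raise, or center that
        PSU's score total at the grand mean across all PSUs.
    """

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray
    singleton: str = "error"
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.strata = np.asarray(self.strata)
        self.psu = np.asarray(self.psu)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValueError("strata, psu and weights must have equal length")
        if not np.all(self.weights > 0):
            raise ValueError("sampling weights must be strictly positive")
        if self.singleton not in ("error", "center"):
            raise ValueError("singleton must be 'error' or 'center'")
        # integer codes for fast groupby: PSU ids are nested within strata
        s_codes, self._strata_labels = pd.factorize(self.strata)
        pair = pd.MultiIndex.from_arrays([self.strata, self.psu])
        p_codes, pairs = pd.factorize(pair)
        self._s_codes = s_codes
        self._p_codes = p_codes
        self._n_psu = len(pairs)
        self._n_strata = len(self._strata_labels)
        # stratum of each PSU
        psu_stratum = np.empty(self._n_psu, dtype=int)
        psu_stratum[p_codes] = s_codes
        self._psu_stratum = psu_stratum
        self._psu_per_stratum = np.bincount(psu_stratum, minlength=self._n_strata)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strata="stratum", psu="psu",
                   weights="weight", singleton="error") -> "SurveyDesign":
        return cls(df[strata].to_numpy(), df[psu].to_numpy(),
                   df[weights].to_numpy(), singleton=singleton)

    def subset(self, mask) -> "SurveyDesign":
        mask = np.asarray(mask)
        return SurveyDesign(self.strata[mask], self.psu[mask],
                            self.weights[mask], singleton=self.singleton)

    def replace_weights(self, weights) -> "SurveyDesign":
        return SurveyDesign(self.strata, self.psu, np.asarray(weights, float),
                            singleton=self.singleton)

    @property
    def n_psu(self) -> int:
        return self._n_psu

    @property
    def n_strata(self) -> int:
        return self._n_strata

    @property
    def design_df(self) -> int:
        """Design degrees of freedom: #PSUs minus #strata."""
        return self._n_psu - self._n_strata

    def linearized_cov(self, scores: np.ndarray) -> np.ndarray:
        """Stratified between-PSU covariance of per-subject score vectors.

        ``scores`` is (n, k); rows are summed to PSU totals, deviations
        are taken from the stratum mean (grand mean for singleton strata
        in 'center' mode) and accumulated with the n_h/(n_h-1) factor.
        """
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[0] != len(self.weights):
            scores = scores.T
        k = scores.shape[1]
        # PSU totals
        totals = np.zeros((self._n_psu, k))
        np.add.at(totals, self._p_codes, scores)
        singles = self._psu_per_stratum < 2
        if singles.any() and self.singleton == "error":
            bad = [str(self._strata_labels[i]) for i in np.flatnonzero(singles)]
            raise SingletonPSUError(
                f"stratum/strata {bad} contain a single PSU; "
                "use singleton='center' to center at the grand mean"
            )
        # stratum means of PSU totals
        strat_sum = np.zeros((self._n_strata, k))
        np.add.at(strat_sum, self._psu_stratum, totals)
        strat_mean = strat_sum / self._psu_per_stratum[:, None]
        center = strat_mean[self._psu_stratum]
        if singles.any():  # center singleton strata at the grand PSU mean
            grand = totals.mean(axis=0)
            single_psu = singles[self._psu_stratum]
            center[single_psu] = grand
        dev = totals - center
        nh = self._psu_per_stratum.astype(float)
        factor = np.where(nh > 1, nh / np.maximum(nh - 1.0, 1.0), 1.0)
        v = (dev * factor[self._psu_stratum, None]).T @ dev
        return v


def _srs_design(n: int) -> SurveyDesign:
    """One stratum, each subject its own PSU, unit weights."""
    return SurveyDesign(np.zeros(n, dtype=int), np.arange(n), np.ones(n))


def design_mean(values, design: SurveyDesign):
    """Design-based mean with linearized SE.

    The estimator is the Horvitz–Thompson ratio sum(w*y)/sum(w); the SE
    comes from the between-PSU variance of the linearized residuals
    ``w_i (y_i - est) / sum(w)`` within strata.

    Returns
    -------
    (estimate, se) : tuple of float
    """
    y = np.asarray(values, dtype=float)
    w = design.weights
    wsum = w.sum()
    est = float(np.sum(w * y) / wsum)
    z = (w * (y - est) / wsum)[:, None]
    var = design.linearized_cov(z)[0, 0]
    return est, float(np.sqrt(var))


def design_proportion(indicator, design: SurveyDesign):
    """Design-based proportion (ratio estimate) with linearized SE."""
    ind = np.asarray(indicator, dtype=float)
    if not np.isin(ind[~np.isnan(ind)], (0.0, 1.0)).all():
        raise ValueError("indicator must be binary")
    return design_mean(ind, design)


def pool_cycle_weights(weights, cycle_count: int):
    """Divide weights by the number of pooled survey cycles.

    When several 2-year release cycles are concatenated, each cycle's
    weights are divided by the number of cycles so the pooled weights
    still sum to one population. Ratio estimates, SEs and p-values are
    invariant to this rescaling; only estimated population totals change.
    """
    if cycle_count < 1:
        raise ValueError("cycle_count must be >= 1")
    return np.asarray(weights, dtype=float) / float(cycle_count)


class SurveyLogisticRegression(BaseEstimator):
    """Pseudo-maximum-likelihood logistic regression for complex surveys.

    Coefficients maximize the sampling-weighted log-likelihood via
    iteratively reweighted least squares; the covariance is the sandwich
    ``B V B`` with bread ``B = (X' W X)^{-1}`` (W the weighted IRLS
    working weights) and meat ``V`` the stratified between-PSU covariance
    of PSU-aggregated weighted score vectors. With equal weights and an
    independent-subject design this reduces to ordinary ML with a robust
    covariance; confidence intervals use a t reference with
    ``design_df = #PSUs - #strata``.

    Parameters
    ----------
    fit_intercept : bool, default=True
    tol : float, default=1e-10
        Convergence tolerance on the max absolute coefficient change.
    max_iter : int, default=100
    max_coef : float, default=50.0
        Declares complete separation when any coefficient passes this.

    Attributes
    ----------
    params_ : ndarray
        Coefficients (intercept first when fitted).
    cov_params_ : ndarray
        Design-based covariance matrix.
    bse_ : ndarray
        Standard errors.
    design_df_ : int
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-10,
                 max_iter: int = 100, max_coef: float = 50.0):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.max_coef = max_coef

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y, design: SurveyDesign | None = None, start_params=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        n = len(y)
        if design is None:
            design = _srs_design(n)
        if len(design.weights) != n:
            raise ValueError("design and data have different lengths")
        Xd = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        k = Xd.shape[1]
        w = design.weights

        beta = np.zeros(k) if start_params is None else np.asarray(start_params, float).copy()
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = np.clip(Xd @ beta, -30, 30)
            p = expit(eta)
            wirls = w * p * (1 - p)
            info = Xd.T @ (Xd * wirls[:, None])
            score = Xd.T @ (w * (y - p))
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
            beta = beta + step
            if np.max(np.abs(beta)) > self.max_coef:
                raise ConvergenceError(
                    "coefficients diverging; response may be completely separated"
                )
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"IRLS did not converge in {self.max_iter} iterations")

        eta = np.clip(Xd @ beta, -30, 30)
        p = expit(eta)
        wirls = w * p * (1 - p)
        info = Xd.T @ (Xd * wirls[:, None])
        bread = np.linalg.inv(info)
        scores = Xd * (w * (y - p))[:, None]     # per-subject weighted score
        meat = design.linearized_cov(scores)
        cov = bread @ meat @ bread
        cov = (cov + cov.T) / 2.0

        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.design_df_ = design.design_df
        self.n_iter_ = it
        self.converged_ = True
        self.n_obs_ = n
        if self.fit_intercept:
            self.intercept_ = beta[0]
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        self._names = None
        return self

    # -- inference -------------------------------------------------------
    def _tcrit(self, level: float) -> float:
        df = max(self.design_df_, 1)
        return float(t_dist.ppf(0.5 + level / 2.0, df))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        tc = self._tcrit(level)
        return np.column_stack([self.params_ - tc * self.bse_,
                                self.params_ + tc * self.bse_])

    def pvalues(self) -> np.ndarray:
        df = max(self.design_df_, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = self.params_ / self.bse_
        return 2.0 * t_dist.sf(np.abs(tvals), df)

    def summary_frame(self, level: float = 0.95, names=None) -> pd.DataFrame:
        """Coefficient table with odds ratios, t-based CI bounds and p-values."""
        k = len(self.params_)
        if names is None:
            names = (["(Intercept)"] if self.fit_intercept else []) + [
                f"x{j}" for j in range(k - int(self.fit_intercept))
            ]
        ci = self.conf_int(level)
        return pd.DataFrame(
            {
                "coef": self.params_,
                "se": self.bse_,
                "or": np.exp(self.params_),
                "or_low": np.exp(ci[:, 0]),
                "or_high": np.exp(ci[:, 1]),
                "p": self.pvalues(),
            },
            index=pd.Index(names, name="term"),
        )

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        p1 = expit(eta)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_weighted_logistic(response, predictors, design: SurveyDesign | None = None,
                          level: float = 0.95, names=None, **kwargs):
    """Convenience wrapper: fit and return (model, summary DataFrame)."""
    model = SurveyLogisticRegression(**kwargs).fit(predictors, response, design=design)
    return model, model.summary_frame(level=level, names=names)
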