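"""Exposure pre-processing: LOD substitution, dilution correction, inverse-normal scores.

Urinary biomarker concentrations are censored at the assay's limit of
detection (LOD) and diluted to a degree that varies subject-to-subject.
The standard work-up applied here is

1. replace censored readings by LOD/2,
2. correct for urine dilution with the log ratio of analyte to urinary
   creatinine, and
3. map the dilution-corrected values to standard-normal scores by a
   rank-based inverse normal transformation,

so that every analyte enters downstream regressions on a common N(0, 1)
scale, with odds ratios interpretable per standard-deviation increase.
Because step 3 depends only on ranks, the units of the analyte and of
creatinine (ng/mL over mg/dL here) cancel: any consistent rescaling of
either leaves the final scores unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "substitute_lod",
    "dilution_correct",
    "inverse_normal",
    "InverseNormalTransformer",
    "transform_exposures",
]

#: supported plotting-position conventions for the rank-to-CDF step
RANK_OFFSETS = ("n+1", "blom", "hazen")


def substitute_lod(concentrations, lod, below_lod=None):
    """Replace below-LOD readings by LOD/2.

    Parameters
    ----------
    concentrations : array-like of float
        Measured concentrations (ng/mL). May contain NaN for values the
        assay flagged as below the detection limit.
    lod : float or array-like
        Limit of detection, scalar or per observation. Must be positive
        wherever a substitution is required.
    below_lod : array-like of bool, optional
        Explicit censoring flags. When omitted, readings that are NaN or
        strictly below the LOD are treated as censored.

    Returns
    -------
    ndarray
        Concentrations with censored entries replaced by ``lod / 2``;
        all other entries are returned unchanged.
    """
    conc = np.asarray(concentrations, dtype=float).copy()
    lod = np.broadcast_to(np.asarray(lod, dtype=float), conc.shape)
    if below_lod is None:
        below_lod = np.isnan(conc) | (conc < lod)
    flags = np.asarray(below_lod, dtype=bool)
    if flags.shape != conc.shape:
        raise ValueError("below_lod flags must match concentrations in shape")
    if np.any(flags & ~(lod > 0)):
        raise ValueError("missing or nonpositive LOD for a censored reading")
    conc[flags] = lod[flags] / 2.0
    return conc


def dilution_correct(concentration, creatinine):
    """Natural log of the analyte-to-creatinine concentration ratio.

    Both inputs must be strictly positive. The base of the logarithm and
    the units of either quantity only shift/scale the result by constants
    and are irrelevant after rank-based normalisation.
    """
    conc = np.asarray(concentration, dtype=float)
    crea = np.asarray(creatinine, dtype=float)
    if np.any(~(conc > 0)) or np.any(~(crea > 0)):
        raise ValueError("dilution correction requires strictly positive inputs")
    return np.log(conc / crea)


def _rank_cdf(ranks: np.ndarray, n: int, offset: str) -> np.ndarray:
    if offset == "n+1":
        return ranks / (n + 1.0)
    if offset == "blom":
        return (ranks - 0.375) / (n + 0.25)
    if offset == "hazen":
        return (ranks - 0.5) / n
    raise ValueError(f"unknown rank offset {offset!r}; choose from {RANK_OFFSETS}")


def inverse_normal(values, offset: str = "n+1"):
    """Rank-based inverse normal transformation to standard-normal scores.

    Values are ranked (average rank on ties), converted to empirical CDF
    points ``u_i = rank_i / (n + 1)`` (default; Blom and Hazen plotting
    positions are selectable), and mapped through the standard-normal
    quantile function. NaNs are ignored for ranking and propagated.

    The output is invariant under any strictly increasing transformation
    of the input. If every value is tied the transformation is undefined;
    a warning is issued and an all-zero vector returned.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("inverse_normal requires at least 2 non-missing values")
    xs = x[mask]
    if np.all(xs == xs[0]):
        warnings.warn("all values tied; inverse-normal scores undefined, returning zeros")
        out[mask] = 0.0
        return out
    ranks = rankdata(xs, method="average")
    out[mask] = norm.ppf(_rank_cdf(ranks, n, offset))
    return out


class InverseNormalTransformer(TransformerMixin, BaseEstimator):
    """Column-wise rank-based inverse normal transformer.

    Each column of ``X`` is independently mapped to standard-normal
    scores from the ranks *of the data passed to transform* (the
    transformation is defined by the sample being transformed, like a
    self-referential quantile normalisation; ``fit`` only records the
    number of features).

    Parameters
    ----------
    offset : {"n+1", "blom", "hazen"}, default="n+1"
        Plotting-position convention for the rank-to-CDF step. The
        default ``rank/(n+1)`` keeps all quantiles finite.
    """

    def __init__(self, offset: str = "n+1"):
        self.offset = offset

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        out = np.column_stack([inverse_normal(X[:, j], self.offset) for j in range(X.shape[1])])
        return out[:, 0] if squeeze else out


def transform_exposures(
    cohort: pd.DataFrame,
    metabolites: list[str],
    lods: dict[str, float],
    creatinine_col: str = "creatinine",
    offset: str = "n+1",
    flag_suffix: str = "_below_lod",
) -> pd.DataFrame:
    """Apply the full transform chain to every metabolite column.

    Runs LOD/2 substitution (using ``<name>_below_lod`` flag columns when
    present, otherwise comparing against the LOD), dilution correction by
    ``creatinine_col``, and the inverse normal transformation. Returns a
    DataFrame of standard-normal scores with columns ``z_<name>``,
    indexed like ``cohort``.
    """
    z = {}
    crea = cohort[creatinine_col].to_numpy(dtype=float)
    for met in metabolites:
        flags_col = f"{met}{flag_suffix}"
        flags = cohort[flags_col].to_numpy(dtype=bool) if flags_col in cohort else None
        conc = substitute_lod(cohort[met].to_numpy(dtype=float), lods[met], flags)
        z[f"z_{met}"] = inverse_normal(dilution_correct(conc, crea), offset)
    return pd.DataFrame(z, index=cohort.index)
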