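"""Dose-response analysis over standard-deviate exposure categories.

Inverse-normalised exposures are already N(0,1) scores, so binning at
-1, 0 and +1 partitions subjects into four interpretable dose groups
(more than 1 SD below the mean, the two middle SD bands, more than 1 SD
above). The outcome prevalence in each bin is design-corrected; the
trend across bins is tested with the classical Cochran-Armitage
chi-square for linear trend on the unweighted counts (integer scores),
with a design-based weighted-logistic fit on the category index emitted
alongside as a sensitivity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .design import SurveyDesign, SurveyLogisticRegression, design_proportion

__all__ = ["BIN_LABELS", "TrendResult", "bin_by_sd", "cochran_armitage", "trend_analysis"]

#: dose-category labels in increasing order
BIN_LABELS = ["<=-1 SD", "(-1,0] SD", "(0,1] SD", ">+1 SD"]


@dataclass
class TrendResult:
    table: pd.DataFrame           # per-bin n, cases, raw and weighted prevalence
    statistic: float              # Cochran-Armitage trend chi-square (1 df)
    p_value: float
    weighted_trend_or: float      # OR per category from weighted logistic
    weighted_trend_p: float


def bin_by_sd(z_values) -> np.ndarray:
    """Assign standard-normal scores to the four SD categories (codes 0-3).

    Boundaries at -1, 0, +1; intervals are left-open/right-closed except
    the lowest, which absorbs everything <= -1 (so z = -1 -> category 0,
    z = 0 -> category 1).
    """
    z = np.asarray(z_values, dtype=float)
    return np.digitize(z, [-1.0, 0.0, 1.0], right=True)


def cochran_armitage(positives, totals, scores=None):
    """Cochran-Armitage chi-square test for linear trend in proportions.

    Parameters
    ----------
    positives, totals : array-like of int
        Outcome-positive counts and group totals per ordered category.
        Zero-total categories are dropped with a warning.
    scores : array-like, optional
        Category scores; default 1..k. The statistic is invariant to
        affine rescaling of the scores.

    Returns
    -------
    (statistic, p_value) : chi-square with 1 df, two-sided.
    """
    r = np.asarray(positives, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(r) != len(n) or len(r) < 2:
        raise ValueError("need >= 2 categories with matching counts")
    if np.any(r > n) or np.any(r < 0):
        raise ValueError("positives must lie between 0 and the category total")
    s = np.arange(1.0, len(n) + 1.0) if scores is None else np.asarray(scores, dtype=float)
    keep = n > 0
    if not keep.all():
        warnings.warn("dropping zero-total categories from the trend test")
        r, n, s = r[keep], n[keep], s[keep]
    N, R = n.sum(), r.sum()
    if R == 0 or R == N:
        return 0.0, 1.0
    sbar = (n * s).sum() / N
    num = (r * (s - sbar)).sum() ** 2
    den = (R / N) * (1 - R / N) * (n * (s - sbar) ** 2).sum()
    if den == 0:
        return 0.0, 1.0
    stat = float(num / den)
    return stat, float(chi2.sf(stat, df=1))


def trend_analysis(
    cohort: pd.DataFrame,
    design: SurveyDesign,
    z_col: str = "z_MOP",
    outcome: str = "selfreport_outcome",
) -> TrendResult:
    """Bin, estimate per-bin design-corrected prevalence, test for trend."""
    cats = bin_by_sd(cohort[z_col].to_numpy())
    y = cohort[outcome].to_numpy(dtype=float)
    rows = []
    for c, label in enumerate(BIN_LABELS):
        m = cats == c
        if m.sum() == 0:
            rows.append({"category": label, "n": 0, "cases": 0,
                         "prevalence_raw": np.nan, "prevalence_weighted": np.nan,
                         "prevalence_se": np.nan})
            continue
        try:
            est, se = design_proportion(y[m], design.subset(m))
        except ValueError:      # singleton-PSU subset: keep the point estimate
            w = design.weights[m]
            est, se = float(np.sum(w * y[m]) / w.sum()), np.nan
        rows.append({
            "category": label, "n": int(m.sum()), "cases": int(y[m].sum()),
            "prevalence_raw": float(y[m].mean()),
            "prevalence_weighted": est, "prevalence_se": se,
        })
    table = pd.DataFrame(rows).set_index("category")
    stat, p = cochran_armitage(table["cases"].to_numpy(), table["n"].to_numpy())
    # design-based check: logistic on the category index
    fit = SurveyLogisticRegression().fit(cats.astype(float)[:, None], y, design=design)
    sf = fit.summary_frame().iloc[1]
    return TrendResult(table=table, statistic=stat, p_value=p,
                       weighted_trend_or=float(sf["or"]), weighted_trend_p=float(sf["p"]))
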