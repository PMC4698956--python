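"""Validation of the self-reported outcome against imaging grades.

A binary self-report ("has a doctor ever told you diabetes affected
your eyes / you had retinopathy") is cross-tabulated against a 4-level
fundus-photography grade (none, mild NPR, moderate/severe NPR, PR)
available only in a substudy. The 4-level table is collapsed to 2x2
with "imaging-positive" meaning moderate/severe NPR or PR — mild NPR is
counted with "none" because mild disease is unlikely to have prompted a
physician's remark. From the collapsed table come percent agreement,
Cohen's kappa (chance-corrected agreement) with a large-sample SE and a
test of kappa = 0, and the two misclassification rates the sensitivity
simulation consumes: the share of self-report-positives without imaging
confirmation and the share of self-report-negatives with confirmed
moderate-or-worse disease. Both raw and design-weighted versions are
reported; they can differ appreciably under unequal weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .design import SurveyDesign

__all__ = [
    "IMAGING_GRADES",
    "POSITIVE_GRADES",
    "AgreementTable",
    "AgreementResult",
    "MisclassRates",
    "crosstab",
    "cohens_kappa",
    "extract_misclass_rates",
]

#: imaging grade labels, ordered by severity
IMAGING_GRADES = ["none", "mild_npr", "modsev_npr", "pr"]
#: grades counted as imaging-confirmed ("positive") disease
POSITIVE_GRADES = ("modsev_npr", "pr")


@dataclass
class AgreementTable:
    """Cross-tabulation of imaging grade (rows) by self-report (columns)."""

    counts_4x2: pd.DataFrame          # 4 grades x {selfreport 0, 1}
    collapsed_2x2: pd.DataFrame       # {neg, pos} x {selfreport 0, 1}
    row_prop_selfreport: pd.Series    # design-weighted P(selfreport=1 | grade)
    collapsed_row_prop: pd.Series
    n_total: int


@dataclass
class AgreementResult:
    percent_agreement: float          # observed agreement, percent
    expected_agreement: float         # chance agreement, proportion
    kappa: float
    kappa_se: float
    kappa_p: float
    kappa_weighted: float | None = None
    percent_agreement_weighted: float | None = None


@dataclass
class MisclassRates:
    fp_rate: float                    # weighted share of selfreport+ without imaging+
    fn_rate: float                    # weighted share of selfreport- with imaging+
    fp_rate_raw: float
    fn_rate_raw: float


def _collapse(counts_4x2: pd.DataFrame) -> pd.DataFrame:
    pos = [g for g in counts_4x2.index if g in POSITIVE_GRADES]
    neg = [g for g in counts_4x2.index if g not in POSITIVE_GRADES]
    return pd.DataFrame(
        [counts_4x2.loc[neg].sum(), counts_4x2.loc[pos].sum()],
        index=pd.Index(["imaging_neg", "imaging_pos"], name="imaging"),
    )


def crosstab(selfreport, imaging_grade, design: SurveyDesign | None = None) -> AgreementTable:
    """Tabulate self-report against imaging grade in the substudy.

    Rows missing either outcome are excluded. Row proportions of
    self-report-positive are design-weighted when a design is given
    (subset to the tabulated rows), raw otherwise.
    """
    sr = pd.Series(np.asarray(selfreport, dtype=float))
    gr = pd.Series(np.asarray(imaging_grade, dtype=object))
    keep = (~sr.isna()) & (~gr.isna()) & (gr != "missing")
    if keep.sum() == 0:
        raise ValueError("validation subsample is empty")
    sr, gr = sr[keep].astype(int), gr[keep]

    counts = pd.crosstab(gr, sr).reindex(
        index=IMAGING_GRADES, columns=[0, 1], fill_value=0
    )
    counts.index.name = "imaging"
    counts.columns.name = "selfreport"
    collapsed = _collapse(counts)

    def _row_props(groups: pd.Series) -> pd.Series:
        props = {}
        for label in groups.unique():
            m = (groups == label).to_numpy()
            if design is not None:
                sub = design.subset(keep.to_numpy())
                w = sub.weights[m]
                props[label] = float(np.sum(w * sr.to_numpy()[m]) / np.sum(w))
            else:
                props[label] = float(sr.to_numpy()[m].mean())
        return pd.Series(props)

    row_prop = _row_props(gr).reindex(IMAGING_GRADES)
    coll_grp = gr.map(lambda g: "imaging_pos" if g in POSITIVE_GRADES else "imaging_neg")
    coll_prop = _row_props(coll_grp).reindex(["imaging_neg", "imaging_pos"])
    return AgreementTable(counts, collapsed, row_prop, coll_prop, int(keep.sum()))


def cohens_kappa(table, weights_table=None) -> AgreementResult:
    """Cohen's kappa for a 2x2 (or kxk square) agreement table.

    ``table`` holds raw counts with raters on the two axes in the same
    category order. The point estimate, its large-sample SE and the
    two-sided p-value for kappa = 0 come from the standard asymptotic
    theory. An optional design-weighted variant replaces counts by
    weight sums (point estimate only; its sampling theory is not the
    simple-random-sample one, so no SE is attached).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] != tab.shape[1]:
        raise ValueError("agreement table must be square (collapse first)")
    n = tab.sum()
    if n <= 0:
        raise ValueError("agreement table is empty")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("degenerate margin: a category is entirely absent; kappa undefined")
    res = _sm_kappa(tab, return_results=True)
    po = float(np.diag(tab).sum() / n)
    pe = float((tab.sum(axis=0) / n) @ (tab.sum(axis=1) / n))
    out = AgreementResult(
        percent_agreement=100.0 * po,
        expected_agreement=pe,
        kappa=float(res.kappa),
        kappa_se=float(res.std_kappa),
        kappa_p=float(res.pvalue_two_sided),
    )
    if weights_table is not None:
        wt = np.asarray(weights_table, dtype=float)
        if wt.shape != tab.shape:
            raise ValueError("weights_table must match table in shape")
        wn = wt.sum()
        wpo = float(np.diag(wt).sum() / wn)
        wpe = float((wt.sum(axis=0) / wn) @ (wt.sum(axis=1) / wn))
        out.kappa_weighted = (wpo - wpe) / (1.0 - wpe)
        out.percent_agreement_weighted = 100.0 * wpo
    return out


def weighted_agreement_table(selfreport, imaging_grade, design: SurveyDesign) -> np.ndarray:
    """Collapsed 2x2 table of weight sums (imaging-neg/pos x selfreport 0/1)."""
    sr = np.asarray(selfreport, dtype=int)
    pos = np.isin(np.asarray(imaging_grade, dtype=object), POSITIVE_GRADES)
    w = design.weights
    tab = np.zeros((2, 2))
    for i, img in enumerate((~pos, pos)):
        for j, rep in enumerate((sr == 0, sr == 1)):
            tab[i, j] = w[img & rep].sum()
    return tab


def extract_misclass_rates(selfreport, imaging_grade,
                           design: SurveyDesign | None = None) -> MisclassRates:
    """Misclassification rates of self-report against the imaging standard.

    fp_rate: among self-report-positives, the (design-weighted) share
    without moderate/severe NPR or PR on imaging. fn_rate: among
    self-report-negatives, the share with such imaging findings. Raw
    (unweighted) shares are returned alongside.
    """
    sr = np.asarray(selfreport, dtype=int)
    pos = np.isin(np.asarray(imaging_grade, dtype=object), POSITIVE_GRADES)
    rep_pos, rep_neg = sr == 1, sr == 0
    if rep_pos.sum() == 0 or rep_neg.sum() == 0:
        raise ValueError("zero denominator: a self-report category is empty")
    fp_raw = float((~pos & rep_pos).sum() / rep_pos.sum())
    fn_raw = float((pos & rep_neg).sum() / rep_neg.sum())
    if design is None:
        fp_w, fn_w = fp_raw, fn_raw
    else:
        w = design.weights
        fp_w = float(np.sum(w[rep_pos] * ~pos[rep_pos]) / w[rep_pos].sum())
        fn_w = float(np.sum(w[rep_neg] * pos[rep_neg]) / w[rep_neg].sum())
    return MisclassRates(fp_rate=fp_w, fn_rate=fn_w, fp_rate_raw=fp_raw, fn_rate_raw=fn_raw)
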