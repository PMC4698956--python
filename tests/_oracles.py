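"""Independent brute-force oracles, deliberately written with plain loops
and a different optimiser than the package so they share no code path
with the implementation they check."""

import math

import numpy as np
from scipy.optimize import minimize


def oracle_proportion(y, w, strata, psu):
    """Weighted proportion and Taylor-linearized SE, loop by loop."""
    y, w = list(map(float, y)), list(map(float, w))
    wsum = sum(w)
    est = sum(wi * yi for wi, yi in zip(w, y)) / wsum
    z = [wi * (yi - est) / wsum for wi, yi in zip(w, y)]
    var = 0.0
    for h in sorted(set(strata)):
        idx_h = [i for i, s in enumerate(strata) if s == h]
        psus = sorted(set(psu[i] for i in idx_h))
        totals = [sum(z[i] for i in idx_h if psu[i] == j) for j in psus]
        nh = len(totals)
        mean = sum(totals) / nh
        var += nh / (nh - 1) * sum((t - mean) ** 2 for t in totals)
    return est, math.sqrt(var)


def oracle_weighted_logit(y, X, w, strata=None, psu=None):
    """Pseudo-ML logistic fit by direct likelihood optimisation (BFGS, not
    IRLS) plus a loop-coded stratified sandwich covariance.

    Returns (beta, cov) with an intercept prepended.
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    w = np.asarray(w, float)

    def negll(beta):
        eta = X @ beta
        # log(1+exp(eta)) - y*eta, weighted
        return np.sum(w * (np.logaddexp(0.0, eta) - y * eta))

    res = minimize(negll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    beta = res.x
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    k = X.shape[1]
    info = np.zeros((k, k))
    for i in range(len(y)):
        info += w[i] * p[i] * (1 - p[i]) * np.outer(X[i], X[i])
    bread = np.linalg.inv(info)

    if strata is None:
        strata = [0] * len(y)
        psu = list(range(len(y)))
    scores = [(w[i] * (y[i] - p[i])) * X[i] for i in range(len(y))]
    meat = np.zeros((k, k))
    for h in sorted(set(strata)):
        idx_h = [i for i, s in enumerate(strata) if s == h]
        psus = sorted(set(psu[i] for i in idx_h))
        totals = []
        for j in psus:
            t = np.zeros(k)
            for i in idx_h:
                if psu[i] == j:
                    t += scores[i]
            totals.append(t)
        nh = len(totals)
        mean = sum(totals) / nh
        for t in totals:
            meat += nh / (nh - 1) * np.outer(t - mean, t - mean)
    return beta, bread @ meat @ bread


def oracle_kappa(table):
    """Cohen's kappa by the direct definition."""
    t = np.asarray(table, float)
    n = t.sum()
    po = np.trace(t) / n
    pe = sum(t[i].sum() * t[:, i].sum() for i in range(t.shape[0])) / n**2
    return (po - pe) / (1 - pe)


def oracle_cochran_armitage(r, n, s=None):
    """Trend chi-square from the textbook formula, coded independently."""
    r, n = np.asarray(r, float), np.asarray(n, float)
    s = np.arange(1, len(n) + 1, dtype=float) if s is None else np.asarray(s, float)
    N, R = n.sum(), r.sum()
    num = (N * (r * s).sum() - R * (n * s).sum()) ** 2
    den = R * (N - R) * (N * (n * s**2).sum() - (n * s).sum() ** 2)
    return N * num / den
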