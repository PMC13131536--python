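"""Closed-form and quadrature reference computations.

These are the independent checks for the discretized-diffusion approximation:
the exact multivariate-normal machinery that is tractable only for very small
trees (its intractability at realistic N being the reason the approximation
exists).  Nothing here is used in the main fitting path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

from .treesim import Tree

__all__ = [
    "bm_cov",
    "bm_logdensity",
    "threshold_prob_smallN",
    "semithreshold_logdensity_smallN",
]

_MVN_OPTS = dict(abseps=1e-8, releps=0.0)


def bm_cov(tree: Tree, sigma2: float = 1.0) -> np.ndarray:
    """BM tip covariance: sigma2 times the height of each pair's common ancestor.

    Rows/columns follow ``tree.tip_labels`` order; the diagonal holds the tip
    heights times sigma2.
    """
    tips = tree.tip_ids
    h = tree.heights()
    N = tips.size
    C = np.zeros((N, N))
    for i in range(N):
        C[i, i] = h[tips[i]]
        for j in range(i + 1, N):
            C[i, j] = C[j, i] = h[tree.mrca(tips[i], tips[j])]
    return sigma2 * C


def bm_logdensity(tree: Tree, x0: float, sigma2: float, x) -> float:
    """Exact multivariate-normal log density of tip values under unbounded BM."""
    x = np.asarray(x, dtype=float)
    C = bm_cov(tree, sigma2)
    return float(multivariate_normal(mean=np.full(x.size, x0), cov=C).logpdf(x))


def threshold_prob_smallN(tree: Tree, thresholds, tip_levels, root_liability: float,
                          sigma2: float = 1.0) -> float:
    """Exact probability of ordered discrete tip states under the threshold model.

    The probability is the MVN rectangle integral over the product of the tip
    liability intervals (Genz quadrature); practical only for small N.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    edges = np.concatenate([[-np.inf], thresholds, [np.inf]])
    labels = tree.tip_labels
    if len(labels) > 4:
        raise ValueError("quadrature oracle limited to N <= 4 taxa")
    levels = np.asarray([tip_levels[lab] for lab in labels], dtype=np.int64)
    lower = edges[levels]
    upper = edges[levels + 1]
    C = bm_cov(tree, sigma2)
    mean = np.full(len(labels), root_liability)
    return float(multivariate_normal.cdf(upper, mean=mean, cov=C,
                                         lower_limit=lower, **_MVN_OPTS))


def semithreshold_logdensity_smallN(tree: Tree, x0: float, sigma2: float,
                                    clamp, observations) -> float:
    """Exact mixed density x probability for the semi-threshold model.

    Point tips contribute the MVN density at their values; censored tips the
    conditional (given the point tips) MVN probability of the corresponding
    semi-infinite interval.
    """
    low, high = clamp
    labels = tree.tip_labels
    if len(labels) > 4:
        raise ValueError("quadrature oracle limited to N <= 4 taxa")
    by_taxon = {o.taxon: o for o in observations}
    obs = [by_taxon[lab] for lab in labels]
    C = bm_cov(tree, sigma2)
    mean = np.full(len(labels), x0)
    pt = np.array([o.kind == "point" for o in obs])
    if pt.all():
        x = np.array([o.value for o in obs])
        return float(multivariate_normal(mean=mean, cov=C).logpdf(x))
    # low-censored means liability <= low, high-censored means liability >= high
    cens = [o for o in obs if o.kind == "censored"]
    lo = np.array([-np.inf if o.side == "low" else high for o in cens])
    hi = np.array([low if o.side == "low" else np.inf for o in cens])
    if not pt.any():
        if len(cens) == 1:
            d = norm(loc=mean[0], scale=np.sqrt(C[0, 0]))
            return float(np.log(d.cdf(hi[0]) - d.cdf(lo[0])))
        return float(np.log(multivariate_normal.cdf(
            hi, mean=mean, cov=C, lower_limit=lo, **_MVN_OPTS)))
    x = np.array([o.value for o in obs if o.kind == "point"])
    Caa = C[np.ix_(pt, pt)]
    Cbb = C[np.ix_(~pt, ~pt)]
    Cba = C[np.ix_(~pt, pt)]
    log_f = multivariate_normal(mean=mean[pt], cov=Caa).logpdf(x)
    sol = np.linalg.solve(Caa, x - mean[pt])
    cond_mean = mean[~pt] + Cba @ sol
    cond_cov = Cbb - Cba @ np.linalg.solve(Caa, Cba.T)
    if len(cens) == 1:
        d = norm(loc=cond_mean[0], scale=np.sqrt(cond_cov[0, 0]))
        log_p = np.log(d.cdf(hi[0]) - d.cdf(lo[0]))
    else:
        log_p = np.log(multivariate_normal.cdf(
            hi, mean=cond_mean, cov=cond_cov, lower_limit=lo, **_MVN_OPTS))
    return float(log_f + log_p)
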