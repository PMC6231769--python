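"""Negative-binomial count statistics shared across the pipeline.

Provides median-of-ratios size factors, a method-of-moments dispersion
estimate shrunk toward a fitted mean-dispersion trend, and a two-group
Wald test on the NB mean.  The test is used one-sided for the elongation
"jump" evidence and two-sided for differential accessibility and tissue
bias, so both p-values are returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_LN2 = np.log(2.0)

#: floor/ceiling for the per-site dispersion estimate
DISPERSION_BOUNDS = (1e-8, 10.0)

#: pseudo-count added to normalized group means inside the log fold change
LFC_PSEUDOCOUNT = 0.5


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, elementwise >= p)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a sites x samples count matrix.

    Sites with a zero in any sample are excluded from the median.  If fewer
    than 10 all-positive sites exist the geometric mean is instead computed
    over positive entries only (poscounts-style fallback), so sparse count
    matrices still normalize sensibly.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (sites x samples)")
    if counts.shape[0] == 0:
        return np.ones(counts.shape[1])
    allpos = np.all(counts > 0, axis=1)
    if allpos.sum() >= 10:
        sub = counts[allpos]
        loggeo = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - loggeo[:, None], axis=0))
    else:
        import warnings

        with np.errstate(divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            logc = np.where(counts > 0, np.log(counts), np.nan)
            loggeo = np.nanmean(logc, axis=1)
            ratios = logc - loggeo[:, None]
            if np.all(np.isnan(ratios)):
                return np.ones(counts.shape[1])
            factors = np.exp(np.nanmedian(ratios, axis=0))
    factors = np.where(np.isfinite(factors) & (factors > 0), factors, 1.0)
    # rescale so the geometric mean of factors is 1 (identifiability)
    return factors / np.exp(np.mean(np.log(factors)))


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative sites."""
    keep = (mu > 0) & (alpha > 0) & np.isfinite(alpha)
    if keep.sum() < 3:
        return 0.01, 1.0
    x = 1.0 / mu[keep]
    y = alpha[keep]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0 = float(np.clip(coef[0], 0.0, DISPERSION_BOUNDS[1]))
    a1 = float(np.clip(coef[1], 0.0, None))
    if a0 == 0.0 and a1 == 0.0:
        a0 = 0.01
    return a0, a1


def estimate_dispersions(
    qA: np.ndarray, qB: np.ndarray, shrinkage_weight: float = 0.5
) -> np.ndarray:
    """Per-site NB dispersion from normalized counts of the two groups.

    Method-of-moments on the pooled within-group variance, then a weighted
    average with the value of the fitted mean-dispersion trend (default
    weight 0.5 each).
    """
    mu = np.concatenate([qA, qB], axis=1).mean(axis=1)
    varA = qA.var(axis=1, ddof=1) if qA.shape[1] > 1 else np.zeros(qA.shape[0])
    varB = qB.var(axis=1, ddof=1) if qB.shape[1] > 1 else np.zeros(qB.shape[0])
    pooled_var = 0.5 * (varA + varB)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - mu) / mu**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, 0.0, DISPERSION_BOUNDS[1])
    a0, a1 = _fit_dispersion_trend(mu, alpha_mom)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    w = shrinkage_weight
    alpha = (1.0 - w) * alpha_mom + w * trend
    return np.clip(alpha, *DISPERSION_BOUNDS)


@dataclass
class NBTestResult:
    """Vectorized result of the two-group NB Wald test."""

    lfc: np.ndarray          # log2((meanB + 0.5) / (meanA + 0.5)), normalized scale
    p_greater: np.ndarray    # one-sided, H1: B > A
    p_twosided: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    dispersion: np.ndarray


def nb_two_group_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    shrinkage_weight: float = 0.5,
) -> NBTestResult:
    """Wald test for a difference in NB means between groups A and B.

    ``counts_a``/``counts_b`` are sites x replicates matrices of raw counts.
    Size factors are estimated by median-of-ratios across the combined
    matrix; dispersion per site by shrunk method-of-moments; the Wald
    statistic is built on the log2 ratio of pseudo-counted normalized group
    means via the delta method.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if counts_a.shape[0] != counts_b.shape[0]:
        raise ValueError("group matrices must cover the same sites")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    n = counts_a.shape[0]
    combined = np.concatenate([counts_a, counts_b], axis=1)
    sf = size_factors(combined)
    sfA, sfB = sf[: counts_a.shape[1]], sf[counts_a.shape[1]:]
    qA = counts_a / sfA
    qB = counts_b / sfB
    mA = qA.mean(axis=1)
    mB = qB.mean(axis=1)
    alpha = estimate_dispersions(qA, qB, shrinkage_weight)

    # pseudo-counted means inside the variance keep the Wald statistic from
    # exploding when one group is all zeros (anti-conservative otherwise)
    c = LFC_PSEUDOCOUNT
    var_mA = ((mA + c) + alpha * (mA + c) ** 2) / qA.shape[1]
    var_mB = ((mB + c) + alpha * (mB + c) ** 2) / qB.shape[1]
    lfc = np.log2(mB + c) - np.log2(mA + c)
    se = np.sqrt(var_mA / (mA + c) ** 2 + var_mB / (mB + c) ** 2) / _LN2
    allzero = (combined.sum(axis=1) == 0)
    se_safe = np.where(se > 0, se, np.inf)
    z = lfc / se_safe
    p_greater = stats.norm.sf(z)
    p_two = 2.0 * stats.norm.sf(np.abs(z))
    p_two = np.minimum(p_two, 1.0)
    # degenerate rows: no information
    p_greater = np.where(allzero | (se == 0), 1.0, p_greater)
    p_two = np.where(allzero | (se == 0), 1.0, p_two)
    lfc = np.where(allzero, 0.0, lfc)
    assert lfc.shape == (n,)
    return NBTestResult(lfc, p_greater, p_two, mA, mB, alpha)
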