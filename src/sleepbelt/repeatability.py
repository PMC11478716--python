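"""Within-subject repeatability of nightly features.

A Gaussian random-intercept model y_ij = mu + a_i + e_ij is fit by
restricted maximum likelihood; repeatability is the intra-class
correlation R = var(a) / (var(a) + var(e)). Confidence intervals come
from a seeded parametric bootstrap. REML is implemented directly with the
compound-symmetry closed forms (fast enough to bootstrap thousands of
times), and on balanced designs it coincides with the one-way ANOVA
method-of-moments estimator.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .types import InsufficientDataError, RepeatabilityResult


def _group_stats(y: np.ndarray, codes: np.ndarray):
    n_i = np.bincount(codes).astype(float)
    sum_i = np.bincount(codes, weights=y)
    sumsq_i = np.bincount(codes, weights=y ** 2)
    return n_i, sum_i, sumsq_i


def _neg_reml(params: np.ndarray, y: np.ndarray, codes: np.ndarray,
              n_i: np.ndarray) -> float:
    sa, se = np.exp(params)
    d = se + n_i * sa
    sum_i = np.bincount(codes, weights=y)
    mu = np.sum(sum_i / d * 1.0) / np.sum(n_i / d)
    yc = y - mu
    t_i = np.bincount(codes, weights=yc)
    ss_i = np.bincount(codes, weights=yc ** 2)
    quad = np.sum(ss_i / se - sa * t_i ** 2 / (se * d))
    logdet = np.sum((n_i - 1) * np.log(se) + np.log(d))
    reml_adj = np.log(np.sum(n_i / d))
    return 0.5 * (logdet + quad + reml_adj)


def fit_variance_components(y: np.ndarray, subjects: np.ndarray) -> tuple:
    """REML estimates (mu, var_between, var_within) for the random-intercept
    model; falls back to the var_between = 0 boundary when REML prefers it."""
    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(np.asarray(subjects))
    codes = np.asarray(codes)
    n_i, sum_i, _ = _group_stats(y, codes)
    k = len(n_i)
    total_var = max(np.var(y, ddof=1), 1e-12)

    # method-of-moments start values (one-way ANOVA)
    means_i = sum_i / n_i
    grand = y.mean()
    msb = np.sum(n_i * (means_i - grand) ** 2) / max(k - 1, 1)
    msw_num = np.sum((y - means_i[codes]) ** 2)
    msw = msw_num / max(len(y) - k, 1)
    n0 = (len(y) - np.sum(n_i ** 2) / len(y)) / max(k - 1, 1)
    sa0 = max((msb - msw) / max(n0, 1.0), 1e-4 * total_var)
    se0 = max(msw, 1e-4 * total_var)

    res = minimize(_neg_reml, np.log([sa0, se0]), args=(y, codes, n_i),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    sa, se = np.exp(res.x)
    # boundary check: pure-residual model
    bound = _neg_reml(np.log([1e-12 * total_var, max(np.var(y, ddof=1), 1e-12)]),
                      y, codes, n_i)
    if bound < res.fun:
        sa, se = 0.0, float(np.var(y, ddof=1))
    d = se + n_i * sa
    mu = float(np.sum(sum_i / d) / np.sum(n_i / d))
    return mu, float(sa), float(se)


def repeatability(table: pd.DataFrame, feature: str,
                  subject_col: str = "subject_id",
                  n_boot: int = 1000, seed: int = 0) -> RepeatabilityResult:
    """Point estimate and parametric-bootstrap CI of repeatability for one
    feature column of a subject x night table."""
    sub = table[[subject_col, feature]].dropna()
    counts = sub.groupby(subject_col).size()
    if len(counts) < 5:
        raise InsufficientDataError("need at least 5 subjects")
    if (counts >= 2).sum() < 3:
        raise InsufficientDataError("need >= 2 nights for >= 3 subjects")
    y = sub[feature].to_numpy(dtype=float)
    codes, _ = pd.factorize(sub[subject_col])
    mu, sa, se = fit_variance_components(y, codes)
    total = sa + se
    if total <= 0:
        raise InsufficientDataError("zero total variance: repeatability inestimable")
    r_pt = sa / total

    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n_i = np.bincount(codes)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            a = rng.normal(0.0, np.sqrt(sa), len(n_i))
            yb = mu + a[codes] + rng.normal(0.0, np.sqrt(se), len(y))
            _, sab, seb = fit_variance_components(yb, codes)
            boots[b] = sab / (sab + seb) if sab + seb > 0 else 0.0
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return RepeatabilityResult(
        feature=feature, r_pt=float(r_pt), ci=ci,
        var_between=sa, var_within=se,
        n_subjects=int(len(counts)), n_nights=float(counts.mean()),
    )


def summarize_repeatability(results: list[RepeatabilityResult]) -> dict:
    """Median and IQR of R across a channel's feature results."""
    if not results:
        raise InsufficientDataError("no repeatability results to summarize")
    rs = np.array([r.r_pt for r in results])
    return {
        "median": float(np.median(rs)),
        "iqr": (float(np.percentile(rs, 25)), float(np.percentile(rs, 75))),
        "n_features": len(rs),
    }
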