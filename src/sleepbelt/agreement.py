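"""Bland-Altman agreement between belt- and PSG-derived whole-night rates."""
from __future__ import annotations

import numpy as np
from scipy import stats

from .types import BlandAltmanResult, InsufficientDataError, PairedMeans


def whole_night_mean_rate(intervals: np.ndarray, unit: str = "ms") -> float:
    """Mean instantaneous rate: the arithmetic mean of per-interval rates
    (60000/RR_ms or 60/BB_s), not the rate of the mean interval."""
    x = np.asarray(intervals, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 intervals")
    if np.any(x <= 0):
        raise ValueError("intervals must be positive")
    if unit == "ms":
        return float(np.mean(60000.0 / x))
    if unit == "s":
        return float(np.mean(60.0 / x))
    raise ValueError("unit must be 'ms' or 's'")


def bland_altman(pairs: list[PairedMeans], loa_z: float = 1.96) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for belt minus PSG differences.

    Bias CI uses the t distribution; the limit-of-agreement CIs use the
    standard approximate SE sqrt(3 sd^2 / n).
    """
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 pairs")
    d = np.array([p.belt_value - p.psg_value for p in pairs])
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = np.sqrt(3.0 * sd ** 2 / n)
    loa_lo = bias - loa_z * sd
    loa_hi = bias + loa_z * sd
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower=loa_lo, loa_upper=loa_hi,
        loa_lower_ci=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_upper_ci=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        sd_diff=sd, n=n,
    )


def bland_altman_plot(pairs: list[PairedMeans], result: BlandAltmanResult,
                      ax=None, units: str = ""):
    """Mean-vs-difference plot with dashed LoA and dotted bias-CI lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = [(p.belt_value + p.psg_value) / 2 for p in pairs]
    diffs = [p.belt_value - p.psg_value for p in pairs]
    ax.scatter(means, diffs, s=18, alpha=0.7)
    ax.axhline(result.bias, ls="--", color="k")
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, ls="--", color="gray")
    for y in result.bias_ci:
        ax.axhline(y, ls=":", color="k", lw=0.8)
    ax.set_xlabel(f"mean of devices {units}")
    ax.set_ylabel(f"belt - psg {units}")
    return ax
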