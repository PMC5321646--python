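"""Method-comparison statistics: Bland-Altman, bias, regression, Holm.

Percent differences are computed against a designated reference method's
values by default (the package convention designates the two-tissue model as
reference); a pair-mean denominator is available as an option.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "bland_altman", "percent_bias",
           "linear_regression", "holm_correct", "RegressionResult"]


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman summary of paired percent differences."""

    mean_pct_diff: float
    loa_low: float
    loa_high: float
    sd_pct_diff: float
    n_pairs: int
    pct_diffs: np.ndarray


def bland_altman(estimates, reference_estimates,
                 denominator: str = "reference") -> AgreementReport:
    """Bland-Altman agreement of paired estimates.

    Per-pair percent difference is ``100*(a - b)/b`` with ``b`` the
    reference method's value (or ``100*(a - b)/mean(a, b)`` with
    ``denominator="pair_mean"``); the 95% limits of agreement are
    mean +- 1.96 SD of the per-pair differences.
    """
    a = np.asarray(estimates, dtype=float)
    b = np.asarray(reference_estimates, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("estimates must be equal-length 1-D vectors")
    if denominator == "reference":
        denom = b
    elif denominator == "pair_mean":
        denom = (a + b) / 2.0
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if np.any(denom == 0):
        raise ZeroDivisionError("zero denominator in percent difference")
    d = 100.0 * (a - b) / denom
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return AgreementReport(mean_pct_diff=mean, loa_low=mean - 1.96 * sd,
                           loa_high=mean + 1.96 * sd, sd_pct_diff=sd,
                           n_pairs=d.size, pct_diffs=d)


def percent_bias(estimates, truths):
    """Per-item and overall percent bias, ``100*(est - truth)/truth``.

    Returns ``(per_item, overall)`` with overall the mean of the per-item
    biases.
    """
    est = np.asarray(estimates, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("estimates and truths must have matching shapes")
    if np.any(truth <= 0):
        raise ZeroDivisionError("truth values must be positive")
    per_item = 100.0 * (est - truth) / truth
    return per_item, float(per_item.mean())


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares with Pearson r and two-sided p for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression requires at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), p=float(res.pvalue),
                            stderr=float(res.stderr))


def holm_correct(p_values, alpha: float = 0.05):
    """Bonferroni-Holm step-down correction.

    Sorts the p-values ascending, compares p_(i) with alpha/(m - i + 1) and
    stops at the first failure; adjusted p-values are the running maximum of
    (m - i + 1) * p_(i), capped at 1.  Returns ``(reject, adjusted)`` in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject_sorted = np.zeros(m, dtype=bool)
    adjusted_sorted = np.empty(m)
    running = 0.0
    failed = False
    for i, idx in enumerate(order):
        running = min(max(running, (m - i) * p[idx]), 1.0)
        adjusted_sorted[i] = running
        if not failed and p[idx] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            failed = True
    reject = np.zeros(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adjusted_sorted
    return reject, adjusted
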