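"""Diagnostic accuracy of a binary (normal/impaired) classifier against a
gold-standard rater.

Implements the statistics of the classical 2×2 validity table — sensitivity,
specificity, predictive values, likelihood ratios, overall accuracy and the
single-threshold ROC AUC — each with a 95% confidence interval by the method
conventionally reported for it:

* sensitivity / specificity / accuracy: exact Clopper–Pearson intervals;
* PPV / NPV: standard logit intervals (Mercaldo et al. 2007), falling back
  to a Wilson continuity-corrected bound when the predictive value is
  degenerate (0% or 100%, where the logit is undefined);
* likelihood ratios: the log method (Altman);
* AUC: Hanley–McNeil.

"Positive" throughout means *impaired* spirometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .interpretation import Pattern

__all__ = [
    "NORMAL",
    "IMPAIRED",
    "Confusion2x2",
    "AccuracyResult",
    "UndefinedStatisticError",
    "dichotomize",
    "build_confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "accuracy",
    "likelihood_ratios",
    "binary_auc",
    "required_n_for_proportion",
    "format_percent",
]

NORMAL = "normal"
IMPAIRED = "impaired"


class UndefinedStatisticError(ZeroDivisionError):
    """Raised when a statistic's denominator is zero."""


def dichotomize(pattern) -> str:
    """Collapse a four-level pattern to normal/impaired.

    Obstructive, spirometric restriction and mixed all count as impaired.
    """
    if isinstance(pattern, Pattern):
        pattern = pattern.value
    if pattern == Pattern.NORMAL.value:
        return NORMAL
    if pattern in (Pattern.OBSTRUCTIVE.value,
                   Pattern.SPIROMETRIC_RESTRICTION.value,
                   Pattern.MIXED.value):
        return IMPAIRED
    raise ValueError(f"unknown pattern label: {pattern!r}")


@dataclass(frozen=True)
class Confusion2x2:
    """Counts of a binary test against a gold standard (positive = impaired)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_confusion(test_labels: Sequence[str], gold_labels: Sequence[str]
                    ) -> Confusion2x2:
    """Tally normal/impaired calls of a test against a gold standard."""
    if len(test_labels) != len(gold_labels):
        raise ValueError(
            f"label sequences differ in length: {len(test_labels)} vs {len(gold_labels)}")
    if len(test_labels) == 0:
        raise ValueError("need at least one pair of labels")
    tp = fp = fn = tn = 0
    for t, g in zip(test_labels, gold_labels):
        if t not in (NORMAL, IMPAIRED):
            raise ValueError(f"unknown test label: {t!r}")
        if g not in (NORMAL, IMPAIRED):
            raise ValueError(f"unknown gold label: {g!r}")
        if t == IMPAIRED and g == IMPAIRED:
            tp += 1
        elif t == IMPAIRED and g == NORMAL:
            fp += 1
        elif t == NORMAL and g == IMPAIRED:
            fn += 1
        else:
            tn += 1
    return Confusion2x2(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class AccuracyResult:
    """Point estimate with CI endpoints; percents on the 0–100 scale."""

    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str
    level: float = 0.95


def _z(level: float) -> float:
    return float(norm.ppf(1.0 - (1.0 - level) / 2.0))


def _clopper_pearson_pct(k: int, n: int, level: float) -> Tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return 100.0 * float(lo), 100.0 * float(hi)


def _wilson_cc(k: int, n: int, level: float) -> Tuple[float, float]:
    """Wilson score interval with continuity correction, on proportions."""
    z = _z(level)
    p = k / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    lo = (2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))) / denom
    hi = (2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))) / denom
    return max(0.0, lo), min(1.0, hi)


def _proportion_result(name: str, k: int, n: int, level: float) -> AccuracyResult:
    if n == 0:
        raise UndefinedStatisticError(f"{name} undefined: empty denominator")
    lo, hi = _clopper_pearson_pct(k, n, level)
    return AccuracyResult(name, 100.0 * k / n, lo, hi, "clopper_pearson", level)


def sensitivity(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """TP/(TP+FN), exact Clopper–Pearson CI."""
    return _proportion_result("sensitivity", c.tp, c.tp + c.fn, level)


def specificity(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """TN/(TN+FP), exact Clopper–Pearson CI."""
    return _proportion_result("specificity", c.tn, c.tn + c.fp, level)


def accuracy(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """(TP+TN)/n, exact Clopper–Pearson CI."""
    return _proportion_result("accuracy", c.tp + c.tn, c.n, level)


def _predictive_value(name: str, k: int, n: int, var_logit: float,
                      level: float) -> AccuracyResult:
    """Standard logit CI for a predictive value.

    ``var_logit`` is the variance of the logit of the predictive value
    propagated from the binomial errors of sensitivity and specificity
    (Mercaldo et al.).  At a degenerate value (0 or 1) the logit is
    undefined and the bound away from the boundary comes from the Wilson
    continuity-corrected interval on the raw proportion.
    """
    if n == 0:
        raise UndefinedStatisticError(f"{name} undefined: empty denominator")
    p = k / n
    if k == 0 or k == n:
        lo, hi = _wilson_cc(k, n, level)
        if k == n:
            hi = 1.0
        else:
            lo = 0.0
        return AccuracyResult(name, 100.0 * p, 100.0 * lo, 100.0 * hi,
                              "wilson_cc", level)
    z = _z(level)
    l = math.log(p / (1.0 - p))
    h = z * math.sqrt(var_logit)
    inv = lambda x: 1.0 / (1.0 + math.exp(-x))
    return AccuracyResult(name, 100.0 * p, 100.0 * inv(l - h), 100.0 * inv(l + h),
                          "standard_logit", level)


def ppv(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """TP/(TP+FP) with a standard logit CI."""
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    if n1 == 0 or n0 == 0:
        # marginal degenerate: fall back to the raw proportion
        return _predictive_value("ppv", c.tp, c.tp + c.fp, math.nan, level)
    se, sp = c.tp / n1, c.tn / n0
    var = math.nan
    if 0 < se and sp < 1:
        var = (1 - se) / se / n1 + sp / (1 - sp) / n0 if se > 0 else math.nan
    return _predictive_value("ppv", c.tp, c.tp + c.fp, var, level)


def npv(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """TN/(TN+FN) with a standard logit CI."""
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    if n1 == 0 or n0 == 0:
        return _predictive_value("npv", c.tn, c.tn + c.fn, math.nan, level)
    se, sp = c.tp / n1, c.tn / n0
    var = math.nan
    if se < 1 and sp > 0:
        var = se / (1 - se) / n1 + (1 - sp) / sp / n0
    return _predictive_value("npv", c.tn, c.tn + c.fn, var, level)


def likelihood_ratios(c: Confusion2x2, level: float = 0.95
                      ) -> Tuple[AccuracyResult, AccuracyResult]:
    """Positive and negative likelihood ratios with log-method CIs.

    +LR = sens/(1−spec); with zero false positives it is infinite and the
    interval is open above.  −LR = (1−sens)/spec; with zero false negatives
    it is exactly 0 and no interval is reported (endpoints are NaN).
    """
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("likelihood ratios need both diseased "
                                      "and non-diseased cases")
    se, sp = c.tp / n1, c.tn / n0
    z = _z(level)

    if sp == 1.0:
        plr = AccuracyResult("plr", math.inf, math.nan, math.inf, "log", level)
    elif se == 0.0:
        plr = AccuracyResult("plr", 0.0, math.nan, math.nan, "log", level)
    else:
        est = se / (1.0 - sp)
        var = 1 / c.tp - 1 / n1 + 1 / c.fp - 1 / n0
        h = z * math.sqrt(var)
        plr = AccuracyResult("plr", est, est * math.exp(-h), est * math.exp(h),
                             "log", level)

    if sp == 0.0:
        nlr = AccuracyResult("nlr", math.inf, math.nan, math.nan, "log", level)
    elif se == 1.0:
        nlr = AccuracyResult("nlr", 0.0, math.nan, math.nan, "log", level)
    else:
        est = (1.0 - se) / sp
        var = 1 / c.fn - 1 / n1 + 1 / c.tn - 1 / n0
        h = z * math.sqrt(var)
        nlr = AccuracyResult("nlr", est, est * math.exp(-h), est * math.exp(h),
                             "log", level)
    return plr, nlr


def binary_auc(c: Confusion2x2, level: float = 0.95) -> AccuracyResult:
    """Trapezoidal AUC of the single-threshold ROC: (sens+spec)/2 on [0,1].

    The ROC of a binary test has one interior operating point; the area
    under the two-segment polygon equals the mean of sensitivity and
    specificity.  CI by Hanley–McNeil.
    """
    n1, n0 = c.tp + c.fn, c.tn + c.fp
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError("AUC needs both diseased and non-diseased cases")
    se, sp = c.tp / n1, c.tn / n0
    a = (se + sp) / 2.0
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    h = _z(level) * math.sqrt(max(var, 0.0))
    return AccuracyResult("auc", a, max(0.0, a - h), min(1.0, a + h),
                          "hanley_mcneil", level)


def required_n_for_proportion(p: float, d: float, level: float = 0.95) -> int:
    """Wald planning sample size: smallest n with z²·p(1−p)/d² ≤ n.

    ``p`` is the anticipated proportion, ``d`` the desired CI half-width on
    the same 0–1 scale.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be > 0")
    z = _z(level)
    return math.ceil(z * z * p * (1.0 - p) / (d * d))


def format_percent(x: float, dp: int = 1) -> str:
    """Render a percentage for reports: round to ``dp`` decimals, but never
    display an inexact value as exactly 100 or 0 (99.97% prints as 99.9,
    not 100.0)."""
    r = round(x, dp)
    step = 10 ** (-dp)
    if r >= 100.0 and x < 100.0:
        r = 100.0 - step
    elif r <= 0.0 and x > 0.0:
        r = step
    return f"{r:.{dp}f}"
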