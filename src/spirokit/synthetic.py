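"""Synthetic spirometry cohorts, simulated raters, and the published count
fixtures used to validate the statistics end-to-end without any download.

The cohort generator works backwards from the rule engine's decision
partition: it first draws a target pattern (and, if impaired, a severity
grade), then samples percent-of-predicted indices and an FEV1/FVC ratio
uniformly *inside* that pattern's region, at least ``boundary_margin`` away
from every decision threshold, and finally back-computes litres from a
plausible predicted FVC.  With a positive margin the generator is an exact
inverse image of the classifier, so round-trip label recovery is exact by
construction; realism of the predicted volumes is explicitly not a goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .agreement import ContingencyTable
from .interpretation import (DEFAULT_THRESHOLDS, Pattern, Severity,
                             SpirometryRecord, Thresholds)

__all__ = [
    "CohortSpec",
    "RaterModel",
    "GenerationError",
    "generate_cohort",
    "generate_cohort_with_truth",
    "simulate_rater",
    "table_fixtures",
    "expected_rater_kappa",
]

PATTERN_ORDER = (Pattern.NORMAL, Pattern.OBSTRUCTIVE,
                 Pattern.SPIROMETRIC_RESTRICTION, Pattern.MIXED)

# Study-like defaults: ~64% normal and at least 10% of each impaired pattern.
DEFAULT_PREVALENCE: Dict[Pattern, float] = {
    Pattern.NORMAL: 0.64,
    Pattern.OBSTRUCTIVE: 0.12,
    Pattern.SPIROMETRIC_RESTRICTION: 0.12,
    Pattern.MIXED: 0.12,
}

# Primary-care-like severity mix among impaired records: mostly mild to
# moderate disease, a small very-severe tail.
DEFAULT_SEVERITY_MIX: Dict[Severity, float] = {
    Severity.MILD: 0.35,
    Severity.MODERATE: 0.25,
    Severity.MODERATELY_SEVERE: 0.20,
    Severity.SEVERE: 0.15,
    Severity.VERY_SEVERE: 0.05,
}


class GenerationError(ValueError):
    """The cohort specification is infeasible (e.g. margin too large)."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``boundary_margin`` is the minimum distance, in percent-of-predicted
    points, between any generated index and the 80% / severity-band
    thresholds; the same margin divided by 100 applies to the FEV1/FVC
    ratio threshold.
    """

    n: int = 118
    pattern_prevalence: Mapping[Pattern, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    severity_mix: Mapping[Severity, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_MIX))
    bd_positive_rate: float = 0.15
    boundary_margin: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be ≥ 0")
        prev = {Pattern(k): float(v) for k, v in self.pattern_prevalence.items()}
        if set(prev) != set(PATTERN_ORDER):
            raise ValueError("pattern_prevalence must cover exactly the four patterns")
        if any(v < 0 for v in prev.values()) or not math.isclose(sum(prev.values()), 1.0,
                                                                 abs_tol=1e-9):
            raise ValueError("pattern prevalences must be non-negative and sum to 1")
        object.__setattr__(self, "pattern_prevalence", prev)
        mix = {Severity(k): float(v) for k, v in self.severity_mix.items()}
        if Severity.NOT_APPLICABLE in mix:
            raise ValueError("severity_mix applies to impaired records only")
        if any(v < 0 for v in mix.values()) or not math.isclose(sum(mix.values()), 1.0,
                                                                abs_tol=1e-9):
            raise ValueError("severity_mix must be non-negative and sum to 1")
        object.__setattr__(self, "severity_mix", mix)
        if not 0.0 <= self.bd_positive_rate <= 1.0:
            raise ValueError("bd_positive_rate must be in [0, 1]")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be ≥ 0")


def _severity_band(grade: Severity, edges: Tuple[float, ...],
                   m: float, cap80: Optional[float]) -> Tuple[float, float]:
    """Uniform sampling interval for the grading index of ``grade``, kept
    ``m`` points inside the band edges and, if ``cap80`` is given, below it."""
    e_vs, e_sev, e_ms, e_mild = edges
    bands = {
        Severity.MILD: (e_mild, 130.0),
        Severity.MODERATE: (e_ms, e_mild),
        Severity.MODERATELY_SEVERE: (e_sev, e_ms),
        Severity.SEVERE: (e_vs, e_sev),
        Severity.VERY_SEVERE: (12.0, e_vs),
    }
    lo, hi = bands[grade]
    lo = lo + m if lo not in (12.0, 130.0) else lo
    hi = hi - m if hi not in (12.0, 130.0) else hi
    if cap80 is not None:
        hi = min(hi, cap80 - m)
    if hi <= lo:
        raise GenerationError(
            f"boundary_margin {m} leaves no room in the {grade.value} band")
    return lo, hi


def _draw_record(i: int, pattern: Pattern, grade: Optional[Severity],
                 bd_arm: str, rng: np.random.Generator, t: Thresholds,
                 m: float) -> SpirometryRecord:
    mr = m / 100.0
    p80 = t.percent_threshold
    r70 = t.ratio_threshold
    ratio_hi_ok = min(0.95, 1.0 - mr)
    if r70 + mr >= ratio_hi_ok or r70 - mr <= 0.30:
        raise GenerationError(f"boundary_margin {m} infeasible for the ratio threshold")

    if pattern is Pattern.NORMAL:
        fvc_pct = rng.uniform(p80 + m, 130.0)
        fev1_pct = rng.uniform(p80 + m, 130.0)
        ratio = rng.uniform(r70 + mr, ratio_hi_ok)
    elif pattern is Pattern.OBSTRUCTIVE:
        fvc_pct = rng.uniform(p80 + m, 130.0)
        ratio = rng.uniform(0.30, r70 - mr)
        lo, hi = _severity_band(grade, t.severity_edges, m, cap80=None)
        fev1_pct = rng.uniform(lo, hi)
    elif pattern is Pattern.SPIROMETRIC_RESTRICTION:
        ratio = rng.uniform(r70 + mr, ratio_hi_ok)
        lo, hi = _severity_band(grade, t.severity_edges, m, cap80=p80)
        fvc_pct = rng.uniform(lo, hi)
        # FEV1% tracks FVC% loosely; it does not enter this branch's rules,
        # but keep it off the 80% boundary for a clean inverse image.
        fev1_pct = float(np.clip(fvc_pct * rng.uniform(0.85, 1.05), 15.0, p80 - m))
    else:  # MIXED
        ratio = rng.uniform(0.30, r70 - mr)
        lo, hi = _severity_band(grade, t.severity_edges, m, cap80=p80)
        fev1_pct = rng.uniform(lo, hi)
        fvc_pct = rng.uniform(max(30.0, fev1_pct * 0.8), p80 - m)

    sex = "male" if rng.random() < 0.5 else "female"
    fvc_pred = rng.uniform(3.3, 6.0) if sex == "male" else rng.uniform(2.4, 4.6)
    fvc_pre = fvc_pct / 100.0 * fvc_pred
    fev1_pre = ratio * fvc_pre
    fev1_pred = 100.0 * fev1_pre / fev1_pct

    if bd_arm == "positive":
        gain = max(t.bd_abs_l, t.bd_pct / 100.0 * fev1_pre) * rng.uniform(1.15, 1.6)
        fev1_post = fev1_pre + gain
        fvc_post = max(fvc_pre, fev1_post) + rng.uniform(0.05, 0.3)
    elif bd_arm == "not_significant":
        fev1_post = fev1_pre * (1.0 + rng.uniform(0.01, 0.5 * t.bd_pct / 100.0))
        fvc_post = fvc_pre * (1.0 + rng.uniform(0.0, 0.5 * t.bd_pct / 100.0))
        fvc_post = max(fvc_post, fev1_post)
    else:  # negative / unmodified
        fev1_post = fev1_pre * (1.0 - rng.uniform(0.0, 0.05))
        fvc_post = fvc_pre * (1.0 - rng.uniform(0.0, 0.05))
        fvc_post = max(fvc_post, fev1_post)

    age = float(rng.integers(40, 71))
    height = rng.uniform(165, 188) if sex == "male" else rng.uniform(150, 175)
    weight = rng.uniform(55, 100)
    return SpirometryRecord(
        subject_id=f"S{i:05d}", sex=sex, age=age, height=round(height, 1),
        weight=round(weight, 1),
        fvc_pre_L=round(fvc_pre, 4), fev1_pre_L=round(fev1_pre, 4),
        fvc_pred_L=round(fvc_pred, 4), fev1_pred_L=round(fev1_pred, 4),
        fvc_post_L=round(fvc_post, 4), fev1_post_L=round(fev1_post, 4),
    )


def generate_cohort_with_truth(spec: CohortSpec,
                               thresholds: Thresholds = DEFAULT_THRESHOLDS
                               ) -> Tuple[List[SpirometryRecord],
                                          List[Pattern], List[Optional[Severity]]]:
    """As :func:`generate_cohort`, also returning the intended pattern and
    severity grade of each record (severity is None for normal records)."""
    m = spec.boundary_margin
    if 2 * m >= 10.0:
        raise GenerationError(
            f"boundary_margin {m} is infeasible: severity bands are 10 points wide")
    rng = np.random.default_rng(spec.seed)
    prev = np.array([spec.pattern_prevalence[p] for p in PATTERN_ORDER])
    sev_grades = list(spec.severity_mix)
    sev_probs = np.array([spec.severity_mix[g] for g in sev_grades])
    records, patterns, grades = [], [], []
    for i in range(spec.n):
        pattern = PATTERN_ORDER[rng.choice(len(PATTERN_ORDER), p=prev)]
        grade = None
        if pattern is not Pattern.NORMAL:
            grade = sev_grades[rng.choice(len(sev_grades), p=sev_probs)]
        u = rng.random()
        if u < spec.bd_positive_rate:
            bd_arm = "positive"
        elif u < spec.bd_positive_rate + (1.0 - spec.bd_positive_rate) / 2.0:
            bd_arm = "not_significant"
        else:
            bd_arm = "negative"
        records.append(_draw_record(i, pattern, grade, bd_arm, rng, thresholds, m))
        patterns.append(pattern)
        grades.append(grade)
    return records, patterns, grades


def generate_cohort(spec: CohortSpec,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS
                    ) -> List[SpirometryRecord]:
    """Draw a reproducible synthetic cohort matching ``spec``.

    Each record's derived indices lie strictly inside its target pattern's
    decision region, ``spec.boundary_margin`` away from every threshold.

    Raises
    ------
    GenerationError
        If the margin leaves an empty sampling interval somewhere.
    """
    return generate_cohort_with_truth(spec, thresholds)[0]


@dataclass(frozen=True)
class RaterModel:
    """Stochastic rater: each true pattern is called through a row-stochastic
    confusion matrix; a call may independently be omitted."""

    categories: Tuple[str, ...]
    confusion: np.ndarray
    omission_rate: float = 0.0

    def __post_init__(self):
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        c = np.asarray(self.confusion, dtype=float)
        object.__setattr__(self, "confusion", c)
        if c.shape != (len(cats), len(cats)):
            raise ValueError("confusion matrix shape must match categories")
        if (c < 0).any() or not np.allclose(c.sum(axis=1), 1.0):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        if not 0.0 <= self.omission_rate < 1.0:
            raise ValueError("omission_rate must be in [0, 1)")

    @classmethod
    def identity(cls, categories: Sequence[str]) -> "RaterModel":
        return cls(tuple(categories), np.eye(len(categories)))

    @classmethod
    def symmetric_error(cls, categories: Sequence[str], error_rate: float,
                        omission_rate: float = 0.0) -> "RaterModel":
        """Correct with probability 1−error_rate; errors spread uniformly
        over the other categories."""
        k = len(categories)
        c = np.full((k, k), error_rate / (k - 1))
        np.fill_diagonal(c, 1.0 - error_rate)
        return cls(tuple(categories), c, omission_rate)


def simulate_rater(truth: Sequence[str], model: RaterModel,
                   seed: Optional[int] = None) -> List[Optional[str]]:
    """Draw one call per true label from the model; omitted calls are None."""
    rng = np.random.default_rng(seed)
    index = {c: i for i, c in enumerate(model.categories)}
    calls: List[Optional[str]] = []
    for label in truth:
        if label not in index:
            raise ValueError(f"true label {label!r} not in model categories")
        if model.omission_rate > 0 and rng.random() < model.omission_rate:
            calls.append(None)
            continue
        j = rng.choice(len(model.categories), p=model.confusion[index[label]])
        calls.append(model.categories[j])
    return calls


def expected_rater_kappa(prevalence: Sequence[float],
                         model: RaterModel) -> float:
    """Closed-form kappa of the model's calls against the truth, in the
    infinite-sample limit: po = Σ_t π_t C_tt, pe = Σ_j π_j (πᵀC)_j."""
    prev = np.asarray(prevalence, dtype=float)
    po = float(prev @ np.diag(model.confusion))
    called = prev @ model.confusion
    pe = float(prev @ called)
    return (po - pe) / (1.0 - pe)


def table_fixtures() -> Dict[str, ContingencyTable]:
    """The validation study's published cross-tabulations as count fixtures.

    Rows are the app's calls, columns the human rater's. ``dichotomous_*``
    are the normal/impaired 2×2 tables (n = 118 each); ``pattern_rater1``
    is 3×3 because that rater folded the mixed pattern into obstructive;
    ``pattern_rater2`` is the full 4×4.
    """
    dich = ("normal", "impaired")
    four = ("normal", "obstructive", "spirometric_restriction", "mixed")
    three = four[:3]
    return {
        "dichotomous_rater1": ContingencyTable(
            dich, [[74, 1], [4, 39]],
            "app vs pulmonologist 1, normal/impaired dichotomy"),
        "dichotomous_rater2": ContingencyTable(
            dich, [[75, 0], [1, 42]],
            "app vs pulmonologist 2, normal/impaired dichotomy"),
        "pattern_rater1": ContingencyTable(
            three, [[74, 1, 0], [1, 23, 1], [3, 1, 14]],
            "app vs pulmonologist 1, three patterns (mixed folded into "
            "obstructive on both sides)"),
        "pattern_rater2": ContingencyTable(
            four, [[75, 0, 0, 0], [0, 11, 0, 0], [1, 0, 14, 3], [0, 1, 0, 13]],
            "app vs pulmonologist 2, four patterns"),
    }
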