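"""Deterministic spirometry interpretation: pattern, severity, reversibility.

The engine maps one subject's pre/post-bronchodilator spirometry to the
standard primary-care interpretation triple:

* **pattern** — normal, obstructive, spirometric restriction, or mixed,
  decided from the FEV1/FVC ratio against a fixed threshold (default 0.70)
  and FVC%/FEV1% of predicted against 80%;
* **severity** — graded from the percent-of-predicted of the index the
  pattern impairs (FEV1% for obstructive/mixed, FVC% for restriction),
  using the SEPAR/ATS-ERS bands mild ≥70, moderate 60–69, moderately
  severe 50–59, severe 35–49, very severe <35;
* **bronchodilator test** — positive when FEV1 or FVC improves by at least
  12% of the pre value *and* at least 0.2 L.

Pattern and severity are decided from pre-bronchodilator values; the
post-bronchodilator pair only feeds the reversibility test.  No rounding is
applied before any threshold comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "Pattern",
    "Severity",
    "SeverityIndex",
    "BronchodilatorOutcome",
    "Flag",
    "Thresholds",
    "SpirometryRecord",
    "DerivedIndices",
    "PatternResult",
    "SeverityGrade",
    "BronchodilatorResult",
    "InterpretationReport",
    "InvalidRecordError",
    "derive_indices",
    "classify_pattern",
    "grade_severity",
    "evaluate_bronchodilator",
    "interpret_record",
]


class InvalidRecordError(ValueError):
    """A spirometry record violates a precondition; names the offending field."""

    def __init__(self, message: str, field_name: Optional[str] = None,
                 subject_id: Optional[str] = None):
        self.field_name = field_name
        self.subject_id = subject_id
        prefix = f"[{subject_id}] " if subject_id else ""
        super().__init__(prefix + message)


class Pattern(str, Enum):
    NORMAL = "normal"
    OBSTRUCTIVE = "obstructive"
    SPIROMETRIC_RESTRICTION = "spirometric_restriction"
    MIXED = "mixed"


class Severity(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"
    VERY_SEVERE = "very_severe"
    NOT_APPLICABLE = "not_applicable"


class SeverityIndex(str, Enum):
    """Which percent-of-predicted index the severity grade was read from."""

    FEV1 = "FEV1"
    FVC = "FVC"
    NONE = "none"


class BronchodilatorOutcome(str, Enum):
    POSITIVE = "positive"
    NOT_SIGNIFICANT = "not_significant"
    NEGATIVE_UNMODIFIED = "negative_unmodified"
    NOT_EVALUABLE = "not_evaluable"


class Flag(str, Enum):
    """Audit flags for records that sit on, or fall between, the published
    pattern definitions.

    BOUNDARY_FVC_80
        FVC% equals the 80% threshold exactly; the published definitions use
        ``>`` for obstruction and ``≥`` for normal, so equality is resolved
        as "not reduced" and flagged.
    NONSPECIFIC_LOW_FEV1
        Preserved ratio and FVC% but FEV1% below 80: meets neither the
        obstructive nor restrictive definition; classified normal, flagged.
    MIXED_FEV1_NOT_REDUCED
        Mixed pattern (low ratio, low FVC%) whose FEV1% is nevertheless ≥80;
        the mixed definition expects a reduced FEV1%.
    """

    BOUNDARY_FVC_80 = "BOUNDARY_FVC_80"
    NONSPECIFIC_LOW_FEV1 = "NONSPECIFIC_LOW_FEV1"
    MIXED_FEV1_NOT_REDUCED = "MIXED_FEV1_NOT_REDUCED"


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the rule engine.

    Attributes
    ----------
    ratio_threshold : float
        Fixed FEV1/FVC cut-off below which airflow is obstructed. 0.70 by
        convention; age-dependent lower-limit-of-normal alternatives are out
        of scope but the value is configurable.
    percent_threshold : float
        Percent-of-predicted below which FVC or FEV1 counts as reduced (80).
    severity_edges : tuple of float
        Band edges (very_severe < 35 ≤ severe < 50 ≤ moderately_severe < 60
        ≤ moderate < 70 ≤ mild); each edge belongs to the higher band.
    bd_pct : float
        Minimum percent improvement over the pre value for a positive
        bronchodilator test (12).
    bd_abs_l : float
        Minimum absolute improvement in litres for a positive test (0.2).
    """

    ratio_threshold: float = 0.70
    percent_threshold: float = 80.0
    severity_edges: tuple = (35.0, 50.0, 60.0, 70.0)
    bd_pct: float = 12.0
    bd_abs_l: float = 0.2

    def __post_init__(self):
        if not (0 < self.ratio_threshold < 1):
            raise ValueError("ratio_threshold must be in (0, 1)")
        if self.percent_threshold <= 0 or self.bd_pct <= 0 or self.bd_abs_l <= 0:
            raise ValueError("thresholds must be positive")
        if list(self.severity_edges) != sorted(self.severity_edges):
            raise ValueError("severity_edges must be increasing")


DEFAULT_THRESHOLDS = Thresholds()


def _check_volume(name: str, value, subject_id, *, positive=False, optional=False):
    if value is None:
        if optional:
            return None
        raise InvalidRecordError(f"missing required field {name!r}", name, subject_id)
    v = float(value)
    if not math.isfinite(v):
        raise InvalidRecordError(f"{name} must be finite, got {value!r}", name, subject_id)
    if positive and v <= 0:
        raise InvalidRecordError(f"{name} must be > 0, got {v}", name, subject_id)
    if v < 0:
        raise InvalidRecordError(f"{name} must be ≥ 0, got {v}", name, subject_id)
    return v


@dataclass(frozen=True)
class SpirometryRecord:
    """One subject's anthropometrics and pre/post-bronchodilator volumes.

    Volumes are in litres; ``*_pred_L`` are the reference (predicted) values
    supplied by the caller (e.g. from GLI-2012 equations, which are not part
    of this package). Post-bronchodilator values are optional as a pair.
    """

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    height: float  # cm
    weight: float  # kg
    fvc_pre_L: float
    fev1_pre_L: float
    fvc_pred_L: float
    fev1_pred_L: float
    fvc_post_L: Optional[float] = None
    fev1_post_L: Optional[float] = None

    def __post_init__(self):
        sid = self.subject_id
        if self.sex not in ("male", "female"):
            raise InvalidRecordError(f"sex must be 'male' or 'female', got {self.sex!r}",
                                     "sex", sid)
        for name in ("age", "height", "weight"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise InvalidRecordError(f"{name} must be > 0, got {v}", name, sid)
        _check_volume("fvc_pre_L", self.fvc_pre_L, sid)
        _check_volume("fev1_pre_L", self.fev1_pre_L, sid)
        _check_volume("fvc_pred_L", self.fvc_pred_L, sid, positive=True)
        _check_volume("fev1_pred_L", self.fev1_pred_L, sid, positive=True)
        _check_volume("fvc_post_L", self.fvc_post_L, sid, optional=True)
        _check_volume("fev1_post_L", self.fev1_post_L, sid, optional=True)
        if float(self.fev1_pre_L) > float(self.fvc_pre_L):
            raise InvalidRecordError(
                f"fev1_pre_L ({self.fev1_pre_L}) exceeds fvc_pre_L ({self.fvc_pre_L}); "
                "FEV1 is a sub-volume of FVC", "fev1_pre_L", sid)

    @property
    def has_post_bd(self) -> bool:
        return self.fvc_post_L is not None and self.fev1_post_L is not None


@dataclass(frozen=True)
class DerivedIndices:
    """Percent-of-predicted FVC and FEV1 and the absolute FEV1/FVC ratio,
    computed from pre-bronchodilator values at full precision."""

    fvc_pct: float
    fev1_pct: float
    ratio: float


@dataclass(frozen=True)
class PatternResult:
    pattern: Pattern
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class SeverityGrade:
    grade: Severity
    index_used: SeverityIndex


@dataclass(frozen=True)
class BronchodilatorResult:
    result: BronchodilatorOutcome
    delta_fev1_L: Optional[float] = None
    delta_fev1_pct: Optional[float] = None
    delta_fvc_L: Optional[float] = None
    delta_fvc_pct: Optional[float] = None


@dataclass(frozen=True)
class InterpretationReport:
    subject_id: str
    indices: DerivedIndices
    pattern_result: PatternResult
    severity: SeverityGrade
    bd_test: BronchodilatorResult

    def to_dict(self) -> dict:
        """JSON-serialisable view; percents rendered at 1 decimal."""
        bd = self.bd_test
        return {
            "subject_id": self.subject_id,
            "indices": {
                "fvc_pct": round(self.indices.fvc_pct, 1),
                "fev1_pct": round(self.indices.fev1_pct, 1),
                "ratio": round(self.indices.ratio, 3),
            },
            "pattern": self.pattern_result.pattern.value,
            "flags": sorted(f.value for f in self.pattern_result.flags),
            "severity": self.severity.grade.value,
            "severity_index": self.severity.index_used.value,
            "bd_test": bd.result.value,
            "bd_delta_fev1_L": None if bd.delta_fev1_L is None else round(bd.delta_fev1_L, 3),
            "bd_delta_fev1_pct": None if bd.delta_fev1_pct is None else round(bd.delta_fev1_pct, 1),
            "bd_delta_fvc_L": None if bd.delta_fvc_L is None else round(bd.delta_fvc_L, 3),
            "bd_delta_fvc_pct": None if bd.delta_fvc_pct is None else round(bd.delta_fvc_pct, 1),
        }


def derive_indices(record: SpirometryRecord) -> DerivedIndices:
    """Compute FVC%, FEV1% of predicted and the FEV1/FVC ratio.

    Raises
    ------
    InvalidRecordError
        If a predicted value is non-positive or the pre-bronchodilator FVC
        is zero (the ratio would be undefined).
    """
    sid = record.subject_id
    if record.fvc_pred_L <= 0:
        raise InvalidRecordError("fvc_pred_L must be > 0", "fvc_pred_L", sid)
    if record.fev1_pred_L <= 0:
        raise InvalidRecordError("fev1_pred_L must be > 0", "fev1_pred_L", sid)
    if record.fvc_pre_L <= 0:
        raise InvalidRecordError("fvc_pre_L must be > 0 to form FEV1/FVC",
                                 "fvc_pre_L", sid)
    return DerivedIndices(
        fvc_pct=100.0 * record.fvc_pre_L / record.fvc_pred_L,
        fev1_pct=100.0 * record.fev1_pre_L / record.fev1_pred_L,
        ratio=record.fev1_pre_L / record.fvc_pre_L,
    )


def classify_pattern(indices: DerivedIndices,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> PatternResult:
    """Assign exactly one of the four patterns from the derived indices.

    The partition is total over (fvc_pct, fev1_pct, ratio).  FVC% equal to
    the 80% threshold counts as "not reduced" in every branch and raises the
    ``BOUNDARY_FVC_80`` audit flag.  A preserved ratio and FVC% with FEV1%
    below 80 ("non-specific" reduction) is classified normal and flagged.
    """
    t = thresholds
    flags = set()
    if indices.fvc_pct == t.percent_threshold:
        flags.add(Flag.BOUNDARY_FVC_80)
    fvc_reduced = indices.fvc_pct < t.percent_threshold
    if indices.ratio < t.ratio_threshold:
        if fvc_reduced:
            pattern = Pattern.MIXED
            if indices.fev1_pct >= t.percent_threshold:
                flags.add(Flag.MIXED_FEV1_NOT_REDUCED)
        else:
            pattern = Pattern.OBSTRUCTIVE
    else:
        if fvc_reduced:
            pattern = Pattern.SPIROMETRIC_RESTRICTION
        else:
            pattern = Pattern.NORMAL
            if indices.fev1_pct < t.percent_threshold:
                flags.add(Flag.NONSPECIFIC_LOW_FEV1)
    return PatternResult(pattern=pattern, flags=frozenset(flags))


def grade_severity(pattern: PatternResult, indices: DerivedIndices,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> SeverityGrade:
    """Grade severity from the index the pattern impairs.

    Obstructive and mixed patterns are graded on FEV1% of predicted,
    spirometric restriction on FVC%; normal records carry no grade.  Band
    edges belong to the higher (milder) band: exactly 70 is mild, exactly
    35 is severe.
    """
    if pattern.pattern is Pattern.NORMAL:
        return SeverityGrade(Severity.NOT_APPLICABLE, SeverityIndex.NONE)
    if pattern.pattern is Pattern.SPIROMETRIC_RESTRICTION:
        x, idx = indices.fvc_pct, SeverityIndex.FVC
    else:  # obstructive or mixed
        x, idx = indices.fev1_pct, SeverityIndex.FEV1
    e_vs, e_sev, e_ms, e_mild = thresholds.severity_edges
    if x >= e_mild:
        grade = Severity.MILD
    elif x >= e_ms:
        grade = Severity.MODERATE
    elif x >= e_sev:
        grade = Severity.MODERATELY_SEVERE
    elif x >= e_vs:
        grade = Severity.SEVERE
    else:
        grade = Severity.VERY_SEVERE
    return SeverityGrade(grade, idx)


def evaluate_bronchodilator(record: SpirometryRecord,
                            thresholds: Thresholds = DEFAULT_THRESHOLDS
                            ) -> BronchodilatorResult:
    """Evaluate reversibility from the pre/post-bronchodilator pair.

    Positive when either FEV1 or FVC improves by ≥ ``bd_pct`` percent of its
    pre value *and* ≥ ``bd_abs_l`` litres; not significant when there is some
    improvement short of that; negative/unmodified when neither index
    improves.  Records without post-bronchodilator values are not evaluable.
    """
    sid = record.subject_id
    if record.fvc_post_L is None and record.fev1_post_L is None:
        return BronchodilatorResult(BronchodilatorOutcome.NOT_EVALUABLE)
    if record.fvc_post_L is None or record.fev1_post_L is None:
        raise InvalidRecordError(
            "post-bronchodilator FVC and FEV1 must be supplied together",
            "fvc_post_L" if record.fvc_post_L is None else "fev1_post_L", sid)
    if record.fev1_pre_L <= 0 or record.fvc_pre_L <= 0:
        raise InvalidRecordError(
            "pre-bronchodilator volumes must be > 0 to express the "
            "bronchodilator response as a percent change", "fev1_pre_L", sid)
    d_fev1 = record.fev1_post_L - record.fev1_pre_L
    d_fvc = record.fvc_post_L - record.fvc_pre_L
    d_fev1_pct = 100.0 * d_fev1 / record.fev1_pre_L
    d_fvc_pct = 100.0 * d_fvc / record.fvc_pre_L
    t = thresholds
    positive = ((d_fev1 >= t.bd_abs_l and d_fev1_pct >= t.bd_pct)
                or (d_fvc >= t.bd_abs_l and d_fvc_pct >= t.bd_pct))
    if positive:
        outcome = BronchodilatorOutcome.POSITIVE
    elif max(d_fev1_pct, d_fvc_pct) > 0:
        outcome = BronchodilatorOutcome.NOT_SIGNIFICANT
    else:
        outcome = BronchodilatorOutcome.NEGATIVE_UNMODIFIED
    return BronchodilatorResult(outcome, d_fev1, d_fev1_pct, d_fvc, d_fvc_pct)


def interpret_record(record: SpirometryRecord,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS
                     ) -> InterpretationReport:
    """Full interpretation: indices → pattern → severity, plus the
    bronchodilator test. Pure and deterministic."""
    indices = derive_indices(record)
    pattern = classify_pattern(indices, thresholds)
    severity = grade_severity(pattern, indices, thresholds)
    bd = evaluate_bronchodilator(record, thresholds)
    return InterpretationReport(record.subject_id, indices, pattern, severity, bd)
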