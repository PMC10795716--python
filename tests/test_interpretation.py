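"""Unit and property tests of the spirometry rule engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spirokit import (
    BronchodilatorOutcome,
    DerivedIndices,
    Flag,
    InvalidRecordError,
    Pattern,
    Severity,
    SeverityIndex,
    SpirometryRecord,
    Thresholds,
    classify_pattern,
    derive_indices,
    evaluate_bronchodilator,
    grade_severity,
    interpret_record,
)


def make_record(fvc_pre=4.0, fev1_pre=3.0, fvc_pred=4.0, fev1_pred=3.0,
                fvc_post=None, fev1_post=None, subject_id="T1"):
    return SpirometryRecord(
        subject_id=subject_id, sex="male", age=55, height=175, weight=80,
        fvc_pre_L=fvc_pre, fev1_pre_L=fev1_pre,
        fvc_pred_L=fvc_pred, fev1_pred_L=fev1_pred,
        fvc_post_L=fvc_post, fev1_post_L=fev1_post)


class TestDeriveIndices:
    def test_identity_case(self):
        idx = derive_indices(make_record())
        assert idx.fvc_pct == 100.0
        assert idx.fev1_pct == 100.0
        assert idx.ratio == 0.75

    def test_exact_ratio(self):
        idx = derive_indices(make_record(fvc_pre=3.2, fev1_pre=2.4))
        assert idx.fvc_pct == 80.0

    def test_zero_predicted_rejected(self):
        with pytest.raises(InvalidRecordError, match="fvc_pred_L"):
            make_record(fvc_pred=0.0)

    def test_full_precision_no_rounding(self):
        idx = derive_indices(make_record(fvc_pre=3.0, fev1_pre=2.0,
                                         fvc_pred=4.1, fev1_pred=3.3))
        assert idx.fvc_pct == pytest.approx(100 * 3.0 / 4.1, abs=0)
        assert idx.ratio == pytest.approx(2.0 / 3.0, abs=0)


class TestRecordValidation:
    def test_fev1_exceeding_fvc_rejected(self):
        with pytest.raises(InvalidRecordError, match="sub-volume"):
            make_record(fvc_pre=2.0, fev1_pre=2.5)

    def test_nonfinite_volume_rejected(self):
        with pytest.raises(InvalidRecordError, match="finite"):
            make_record(fvc_pre=math.inf, fev1_pre=1.0)

    def test_negative_anthropometrics_rejected(self):
        with pytest.raises(InvalidRecordError, match="age"):
            SpirometryRecord("x", "female", -3, 160, 60, 3, 2, 3.5, 2.8)


class TestClassifyPattern:
    @pytest.mark.parametrize("fvc,fev1,ratio,expected", [
        (90, 85, 0.75, Pattern.NORMAL),
        (95, 60, 0.55, Pattern.OBSTRUCTIVE),
        (65, 70, 0.80, Pattern.SPIROMETRIC_RESTRICTION),
        (60, 45, 0.60, Pattern.MIXED),
        # threshold edges: equality counts as preserved/not-obstructed
        (80, 80, 0.70, Pattern.NORMAL),
        (80, 90, 0.69, Pattern.OBSTRUCTIVE),
        (79.999, 90, 0.699, Pattern.MIXED),
        (79.999, 90, 0.70, Pattern.SPIROMETRIC_RESTRICTION),
    ])
    def test_pattern_partition(self, fvc, fev1, ratio, expected):
        res = classify_pattern(DerivedIndices(fvc, fev1, ratio))
        assert res.pattern is expected

    def test_boundary_fvc_flag(self):
        res = classify_pattern(DerivedIndices(80.0, 90.0, 0.65))
        assert res.pattern is Pattern.OBSTRUCTIVE
        assert Flag.BOUNDARY_FVC_80 in res.flags

    def test_nonspecific_low_fev1_flagged_normal(self):
        res = classify_pattern(DerivedIndices(90.0, 75.0, 0.80))
        assert res.pattern is Pattern.NORMAL
        assert Flag.NONSPECIFIC_LOW_FEV1 in res.flags

    def test_mixed_with_preserved_fev1_flagged(self):
        res = classify_pattern(DerivedIndices(75.0, 85.0, 0.65))
        assert res.pattern is Pattern.MIXED
        assert Flag.MIXED_FEV1_NOT_REDUCED in res.flags

    def test_configurable_ratio_threshold(self):
        t = Thresholds(ratio_threshold=0.75)
        res = classify_pattern(DerivedIndices(90, 85, 0.72), t)
        assert res.pattern is Pattern.OBSTRUCTIVE

    @given(fvc=st.floats(0, 200), fev1=st.floats(0, 200),
           ratio=st.floats(0, 1))
    @settings(max_examples=300, deadline=None)
    def test_totality_and_oracle_agreement(self, fvc, fev1, ratio):
        """Every index triple gets exactly one pattern, and it matches the
        flat-chain reference implementation."""
        from conftest import oracle_pattern
        res = classify_pattern(DerivedIndices(fvc, fev1, ratio))
        assert res.pattern.value == oracle_pattern(fvc, fev1, ratio)

    def test_totality_on_threshold_spanning_grid(self):
        """Dense grid including the 80% and 0.70 boundaries: no cell is
        unclassified and each gets exactly one of the four patterns."""
        from conftest import oracle_pattern
        fvc_grid = np.concatenate([np.linspace(0, 200, 41), [79.99, 80.0, 80.01]])
        fev1_grid = np.concatenate([np.linspace(0, 200, 21), [79.99, 80.0, 80.01]])
        ratio_grid = np.concatenate([np.linspace(0, 1, 21), [0.699, 0.7, 0.701]])
        count = 0
        for fvc in fvc_grid:
            for fev1 in fev1_grid:
                for ratio in ratio_grid:
                    res = classify_pattern(DerivedIndices(fvc, fev1, ratio))
                    assert res.pattern in Pattern
                    assert res.pattern.value == oracle_pattern(fvc, fev1, ratio)
                    count += 1
        assert count >= 10_000


class TestGradeSeverity:
    @pytest.mark.parametrize("pattern,fvc,fev1,grade,index", [
        (Pattern.OBSTRUCTIVE, 95, 65, Severity.MODERATE, SeverityIndex.FEV1),
        (Pattern.SPIROMETRIC_RESTRICTION, 30, 40, Severity.VERY_SEVERE, SeverityIndex.FVC),
        (Pattern.MIXED, 60, 45, Severity.SEVERE, SeverityIndex.FEV1),
        (Pattern.NORMAL, 90, 90, Severity.NOT_APPLICABLE, SeverityIndex.NONE),
        # band edges belong to the milder band
        (Pattern.OBSTRUCTIVE, 95, 70, Severity.MILD, SeverityIndex.FEV1),
        (Pattern.OBSTRUCTIVE, 95, 60, Severity.MODERATE, SeverityIndex.FEV1),
        (Pattern.OBSTRUCTIVE, 95, 50, Severity.MODERATELY_SEVERE, SeverityIndex.FEV1),
        (Pattern.OBSTRUCTIVE, 95, 35, Severity.SEVERE, SeverityIndex.FEV1),
        (Pattern.OBSTRUCTIVE, 95, 34.999, Severity.VERY_SEVERE, SeverityIndex.FEV1),
    ])
    def test_grading(self, pattern, fvc, fev1, grade, index):
        from spirokit import PatternResult
        idx = DerivedIndices(fvc, fev1, 0.5 if pattern in
                             (Pattern.OBSTRUCTIVE, Pattern.MIXED) else 0.8)
        res = grade_severity(PatternResult(pattern), idx)
        assert res.grade is grade
        assert res.index_used is index

    @given(x=st.floats(0, 150))
    @settings(max_examples=200, deadline=None)
    def test_bands_partition_every_value(self, x, severity_oracle):
        from spirokit import PatternResult
        res = grade_severity(PatternResult(Pattern.OBSTRUCTIVE),
                             DerivedIndices(90.0, x, 0.5))
        assert res.grade.value == severity_oracle("obstructive", 90.0, x)


class TestBronchodilator:
    @pytest.mark.parametrize("fev1_pre,fev1_post,fvc_pre,fvc_post,expected", [
        (2.00, 2.30, 4.0, 4.0, BronchodilatorOutcome.POSITIVE),       # 15%, 0.3 L
        (2.00, 2.10, 4.0, 4.0, BronchodilatorOutcome.NOT_SIGNIFICANT),  # 5%
        (2.00, 2.00, 4.0, 4.0, BronchodilatorOutcome.NEGATIVE_UNMODIFIED),
        (1.00, 1.15, 4.0, 4.0, BronchodilatorOutcome.NOT_SIGNIFICANT),  # 15% but 0.15 L
        (2.00, 2.20, 4.0, 4.0, BronchodilatorOutcome.NOT_SIGNIFICANT),  # 0.2 L but 10%
        (2.00, 2.24, 4.0, 4.0, BronchodilatorOutcome.POSITIVE),        # 12%, 0.24 L
        (2.00, 1.90, 4.0, 4.60, BronchodilatorOutcome.POSITIVE),       # via FVC: 15%, 0.6 L
        (2.00, 1.90, 4.0, 3.90, BronchodilatorOutcome.NEGATIVE_UNMODIFIED),
    ])
    def test_two_criterion_rule(self, fev1_pre, fev1_post, fvc_pre, fvc_post,
                                expected):
        rec = make_record(fvc_pre=fvc_pre, fev1_pre=fev1_pre,
                          fvc_pred=4.5, fev1_pred=3.5,
                          fvc_post=fvc_post, fev1_post=fev1_post)
        assert evaluate_bronchodilator(rec).result is expected

    def test_missing_post_not_evaluable(self):
        res = evaluate_bronchodilator(make_record())
        assert res.result is BronchodilatorOutcome.NOT_EVALUABLE
        assert res.delta_fev1_L is None

    def test_half_missing_post_rejected(self):
        with pytest.raises(InvalidRecordError, match="together"):
            evaluate_bronchodilator(make_record(fev1_post=2.5))

    @given(fev1_pre=st.floats(0.5, 5), dfev1=st.floats(-0.5, 1.5),
           fvc_pre=st.floats(0.5, 6), dfvc=st.floats(-0.5, 1.5))
    @settings(max_examples=300, deadline=None)
    def test_truth_table_matches_oracle(self, fev1_pre, dfev1, fvc_pre, dfvc,
                                        bd_oracle):
        fvc_pre = max(fvc_pre, fev1_pre)
        rec = make_record(fvc_pre=fvc_pre, fev1_pre=fev1_pre,
                          fvc_pred=6.0, fev1_pred=5.0,
                          fvc_post=max(fvc_pre + dfvc, 0.0),
                          fev1_post=max(fev1_pre + dfev1, 0.0))
        got = evaluate_bronchodilator(rec).result.value
        assert got == bd_oracle(fev1_pre, rec.fev1_post_L, fvc_pre, rec.fvc_post_L)


class TestInterpretRecord:
    def test_normal_composition(self):
        rep = interpret_record(make_record(fvc_post=4.0, fev1_post=3.0))
        assert rep.pattern_result.pattern is Pattern.NORMAL
        assert rep.severity.grade is Severity.NOT_APPLICABLE
        assert rep.bd_test.result is BronchodilatorOutcome.NEGATIVE_UNMODIFIED

    def test_obstructive_with_reversibility(self):
        rec = make_record(fvc_pre=4.0, fev1_pre=2.4,   # ratio 0.6, FEV1% 68.6
                          fvc_pred=4.0, fev1_pred=3.5,
                          fvc_post=4.0, fev1_post=2.8)  # +16.7%, +0.4 L
        rep = interpret_record(rec)
        assert rep.pattern_result.pattern is Pattern.OBSTRUCTIVE
        assert rep.severity.grade is Severity.MODERATE
        assert rep.bd_test.result is BronchodilatorOutcome.POSITIVE

    def test_no_post_bd_still_reports_pattern(self):
        rec = make_record(fvc_pre=2.4, fev1_pre=1.9, fvc_pred=4.0, fev1_pred=3.2)
        rep = interpret_record(rec)
        assert rep.bd_test.result is BronchodilatorOutcome.NOT_EVALUABLE
        assert rep.pattern_result.pattern is Pattern.SPIROMETRIC_RESTRICTION
        assert rep.severity.grade is not Severity.NOT_APPLICABLE

    def test_determinism_repeated_calls_identical(self):
        rec = make_record(fvc_pre=3.1, fev1_pre=1.9, fvc_pred=4.2,
                          fev1_pred=3.3, fvc_post=3.3, fev1_post=2.2)
        assert interpret_record(rec) == interpret_record(rec)
        assert interpret_record(rec).to_dict() == interpret_record(rec).to_dict()

    def test_severity_pattern_cross_invariant(self):
        """Severity is not_applicable iff the pattern is normal."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            fvc_pred, ratio = rng.uniform(2.5, 6), rng.uniform(0.3, 0.95)
            fvc_pre = rng.uniform(0.3, 1.3) * fvc_pred
            rep = interpret_record(make_record(
                fvc_pre=fvc_pre, fev1_pre=ratio * fvc_pre,
                fvc_pred=fvc_pred, fev1_pred=rng.uniform(2, 4.5)))
            is_normal = rep.pattern_result.pattern is Pattern.NORMAL
            assert (rep.severity.grade is Severity.NOT_APPLICABLE) == is_normal
            assert (rep.severity.index_used is SeverityIndex.NONE) == is_normal


def test_engine_agrees_with_flat_chain_oracle_on_random_records(
        pattern_oracle, severity_oracle, bd_oracle):
    """Oracle equivalence on 10^5 random records with a fixed seed."""
    rng = np.random.default_rng(20240104)
    n = 100_000
    fvc_pred = rng.uniform(2.0, 6.5, n)
    fev1_pred = rng.uniform(1.5, 5.0, n)
    fvc_pct = rng.uniform(5, 160, n)
    ratio = rng.uniform(0.05, 1.0, n)
    fvc_pre = fvc_pct / 100 * fvc_pred
    fev1_pre = ratio * fvc_pre
    fev1_pct = 100 * fev1_pre / fev1_pred
    dfev1 = rng.uniform(-0.4, 0.8, n)
    dfvc = rng.uniform(-0.4, 0.8, n)
    for i in range(n):
        rec = SpirometryRecord(
            f"R{i}", "female", 50, 165, 70,
            fvc_pre_L=fvc_pre[i], fev1_pre_L=fev1_pre[i],
            fvc_pred_L=fvc_pred[i], fev1_pred_L=fev1_pred[i],
            fvc_post_L=max(fvc_pre[i] + dfvc[i], 0.0),
            fev1_post_L=max(fev1_pre[i] + dfev1[i], 0.0))
        rep = interpret_record(rec)
        assert rep.pattern_result.pattern.value == pattern_oracle(
            fvc_pct[i], fev1_pct[i], ratio[i])
        assert rep.severity.grade.value == severity_oracle(
            rep.pattern_result.pattern.value, fvc_pct[i], fev1_pct[i])
        assert rep.bd_test.result.value == bd_oracle(
            fev1_pre[i], rec.fev1_post_L, fvc_pre[i], rec.fvc_post_L)
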