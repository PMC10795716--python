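import numpy as np
import pytest

from spirokit import Confusion2x2, table_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return table_fixtures()


@pytest.fixture(scope="session")
def confusion_rater1():
    # app vs pulmonologist 1, normal/impaired
    return Confusion2x2(tp=39, fp=4, fn=1, tn=74)


@pytest.fixture(scope="session")
def confusion_rater2():
    # app vs pulmonologist 2, normal/impaired
    return Confusion2x2(tp=42, fp=1, fn=0, tn=75)


# ---------------------------------------------------------------------------
# Independent reference implementation of the rule engine, written as a flat
# chain of explicit comparisons over the published definitions (the engine
# itself factors the logic differently).
# ---------------------------------------------------------------------------

def oracle_pattern(fvc_pct, fev1_pct, ratio):
    if ratio >= 0.7 and fvc_pct >= 80 and fev1_pct >= 80:
        return "normal"
    if ratio >= 0.7 and fvc_pct >= 80 and fev1_pct < 80:
        return "normal"  # non-specific reduction, classified normal + flag
    if ratio < 0.7 and fvc_pct >= 80:
        return "obstructive"
    if ratio >= 0.7 and fvc_pct < 80:
        return "spirometric_restriction"
    if ratio < 0.7 and fvc_pct < 80:
        return "mixed"
    raise AssertionError("unreachable")


def oracle_severity(pattern, fvc_pct, fev1_pct):
    if pattern == "normal":
        return "not_applicable"
    x = fvc_pct if pattern == "spirometric_restriction" else fev1_pct
    if x >= 70:
        return "mild"
    if 60 <= x < 70:
        return "moderate"
    if 50 <= x < 60:
        return "moderately_severe"
    if 35 <= x < 50:
        return "severe"
    return "very_severe"


def oracle_bd(fev1_pre, fev1_post, fvc_pre, fvc_post):
    if fev1_post is None and fvc_post is None:
        return "not_evaluable"
    d1, d1p = fev1_post - fev1_pre, 100 * (fev1_post - fev1_pre) / fev1_pre
    d2, d2p = fvc_post - fvc_pre, 100 * (fvc_post - fvc_pre) / fvc_pre
    if (d1 >= 0.2 and d1p >= 12) or (d2 >= 0.2 and d2p >= 12):
        return "positive"
    if d1p > 0 or d2p > 0:
        return "not_significant"
    return "negative_unmodified"


@pytest.fixture(scope="session")
def pattern_oracle():
    return oracle_pattern


@pytest.fixture(scope="session")
def severity_oracle():
    return oracle_severity


@pytest.fixture(scope="session")
def bd_oracle():
    return oracle_bd
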