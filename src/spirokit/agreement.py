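"""Cohen's kappa agreement between two raters over categorical spirometry
calls: contingency tables, category merging, severity pooling, Landis–Koch
interpretation, and intra-rater reliability from blinded repeats.

The kappa standard error is the Fleiss–Cohen–Everitt asymptotic formula for
a non-null kappa; the Wald interval kappa ± z·SE is deliberately left
uncapped above 1, matching how symmetric intervals around high agreement are
conventionally reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .interpretation import Severity

__all__ = [
    "ContingencyTable",
    "KappaResult",
    "DegenerateTableError",
    "SeverityNotPooledError",
    "cross_tabulate",
    "merge_categories",
    "pool_severity",
    "POOLED_SEVERITY_GROUPS",
    "cohen_kappa",
    "landis_koch",
    "intra_rater",
    "drop_incomplete_pairs",
]


class DegenerateTableError(ValueError):
    """Kappa is undefined: expected agreement equals 1."""


class SeverityNotPooledError(ValueError):
    """Signal that a case carries no pooled severity group (not_applicable)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Square cross-tabulation of two raters' calls over shared categories.

    Rows index rater A's calls, columns rater B's.
    """

    categories: Tuple[str, ...]
    counts: np.ndarray
    description: Optional[str] = None

    def __post_init__(self):
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if len(cats) < 2:
            raise ValueError("need at least two categories")
        if len(set(cats)) != len(cats):
            raise ValueError("categories must be distinct")
        if c.shape != (len(cats), len(cats)):
            raise ValueError(f"counts shape {c.shape} does not match "
                             f"{len(cats)} categories")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("table must contain at least one case")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    po: float
    pe: float
    n: int
    label: str
    level: float = 0.95


def cross_tabulate(labels_a: Sequence[str], labels_b: Sequence[str],
                   categories: Sequence[str],
                   description: Optional[str] = None) -> ContingencyTable:
    """Build the k×k table counting each (a, b) call combination."""
    if len(labels_a) != len(labels_b):
        raise ValueError(f"label sequences differ in length: "
                         f"{len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) == 0:
        raise ValueError("need at least one pair of calls")
    cats = list(categories)
    if len(cats) < 2:
        raise ValueError("need at least two categories")
    index = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        if a not in index:
            raise ValueError(f"unknown label for rater A: {a!r}")
        if b not in index:
            raise ValueError(f"unknown label for rater B: {b!r}")
        counts[index[a], index[b]] += 1
    return ContingencyTable(tuple(cats), counts, description)


def merge_categories(t: ContingencyTable, merge_map: Mapping[str, str]
                     ) -> ContingencyTable:
    """Merge categories by summing rows and columns into their targets.

    ``merge_map`` must assign every existing category a new one (identity
    entries allowed); the total count is preserved.  New categories keep
    the order of first appearance among the old ones.
    """
    missing = [c for c in t.categories if c not in merge_map]
    if missing:
        raise ValueError(f"merge_map does not cover categories: {missing}")
    new_cats: list = []
    for c in t.categories:
        tgt = merge_map[c]
        if tgt not in new_cats:
            new_cats.append(tgt)
    if len(new_cats) < 2:
        raise ValueError("merge would leave fewer than two categories")
    idx = {c: i for i, c in enumerate(new_cats)}
    counts = np.zeros((len(new_cats), len(new_cats)), dtype=np.int64)
    for i, a in enumerate(t.categories):
        for j, b in enumerate(t.categories):
            counts[idx[merge_map[a]], idx[merge_map[b]]] += t.counts[i, j]
    return ContingencyTable(tuple(new_cats), counts, t.description)


POOLED_SEVERITY_GROUPS = ("mild", "moderate_to_moderately_severe",
                          "severe_to_very_severe")

_POOL = {
    Severity.MILD: POOLED_SEVERITY_GROUPS[0],
    Severity.MODERATE: POOLED_SEVERITY_GROUPS[1],
    Severity.MODERATELY_SEVERE: POOLED_SEVERITY_GROUPS[1],
    Severity.SEVERE: POOLED_SEVERITY_GROUPS[2],
    Severity.VERY_SEVERE: POOLED_SEVERITY_GROUPS[2],
}


def pool_severity(label) -> str:
    """Pool the five severity grades into three groups: (1) mild,
    (2) moderate to moderately severe, (3) severe to very severe.

    Raises
    ------
    SeverityNotPooledError
        For ``not_applicable`` (normal pattern): such cases carry no pooled
        group and are excluded from severity agreement.
    """
    sev = Severity(label)
    if sev is Severity.NOT_APPLICABLE:
        raise SeverityNotPooledError(
            "not_applicable has no pooled severity group")
    return _POOL[sev]


def cohen_kappa(t: ContingencyTable, level: float = 0.95) -> KappaResult:
    """Cohen's kappa with Fleiss–Cohen–Everitt SE and an uncapped Wald CI.

    kappa = (po − pe)/(1 − pe) with po the observed and pe the
    chance-expected agreement proportion from the table marginals.
    """
    n = t.n
    p = t.counts.astype(float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if pe >= 1.0:
        raise DegenerateTableError("expected agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    k1 = 1.0 - kappa
    a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * k1) ** 2
            for i in range(len(row)))
    b = k1 * k1 * sum(p[i, j] * (col[i] + row[j]) ** 2
                      for i in range(len(row)) for j in range(len(row)) if i != j)
    c = (kappa - pe * k1) ** 2
    se = math.sqrt(max(a + b - c, 0.0) / (n * (1.0 - pe) ** 2))

    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    return KappaResult(kappa=kappa, se=se, ci_low=kappa - z * se,
                       ci_high=kappa + z * se, po=po, pe=pe, n=n,
                       label=landis_koch(kappa), level=level)


def landis_koch(kappa: float) -> str:
    """Landis–Koch qualitative band of a kappa value."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa <= 0.0:
        return "none"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost_perfect"


def drop_incomplete_pairs(labels_a: Iterable, labels_b: Iterable
                          ) -> Tuple[list, list]:
    """Pairwise deletion: keep only cases where both raters made a call
    (drop pairs containing None/NaN)."""
    a_out, b_out = [], []
    for a, b in zip(labels_a, labels_b):
        if a is None or b is None:
            continue
        if isinstance(a, float) and math.isnan(a):
            continue
        if isinstance(b, float) and math.isnan(b):
            continue
        a_out.append(a)
        b_out.append(b)
    return a_out, b_out


def intra_rater(pairs: Sequence[Tuple], categories: Sequence[str],
                level: float = 0.95) -> KappaResult:
    """Intra-rater reliability: kappa of a rater's first calls against their
    blinded repeat calls on the same cases (incomplete pairs dropped)."""
    if len(pairs) == 0:
        raise ValueError("need at least one (first, repeat) pair")
    first, repeat = drop_incomplete_pairs((p[0] for p in pairs),
                                          (p[1] for p in pairs))
    if not first:
        raise ValueError("no complete (first, repeat) pairs after dropping "
                         "missing calls")
    return cohen_kappa(cross_tabulate(first, repeat, categories), level=level)
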