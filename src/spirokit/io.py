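"""File input/output, study configuration, and the study-reproduction
pipeline that ties the rule engine and the statistics together.

Record files are one row per subject, CSV or JSON-lines, with the column
names of :class:`~spirokit.interpretation.SpirometryRecord` (documented in
``RECORD_COLUMNS``).  A percent-of-predicted mode accepts ``fvc_pct``,
``fev1_pct`` and ``ratio`` directly in place of litres.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .accuracy import (AccuracyResult, Confusion2x2, accuracy, binary_auc,
                       likelihood_ratios, npv, ppv, sensitivity, specificity)
from .agreement import ContingencyTable, KappaResult, cohen_kappa
from .interpretation import (DEFAULT_THRESHOLDS, InterpretationReport,
                             InvalidRecordError, SpirometryRecord, Thresholds,
                             interpret_record)
from .synthetic import table_fixtures

__all__ = [
    "RECORD_COLUMNS",
    "PERCENT_COLUMNS",
    "StudyConfig",
    "RecordValidationError",
    "ReferencePredictor",
    "read_records",
    "write_records",
    "read_calls",
    "interpret_records",
    "reports_to_frame",
    "confusion_from_table",
    "validity_report",
    "kappa_report",
    "reproduce_study",
    "bundle_json",
    "setup_logging",
]

log = logging.getLogger("spirokit")

RECORD_COLUMNS = ("subject_id", "sex", "age", "height", "weight",
                  "fvc_pre_L", "fev1_pre_L", "fvc_pred_L", "fev1_pred_L",
                  "fvc_post_L", "fev1_post_L")
PERCENT_COLUMNS = ("subject_id", "fvc_pct", "fev1_pct", "ratio")

# A reference predictor maps (sex, age, height, weight) to predicted
# (FVC, FEV1) in litres. None is shipped; users may register their own
# (e.g. GLI-2012) to fill in missing predicted values.
ReferencePredictor = Callable[[str, float, float, float], Tuple[float, float]]


class RecordValidationError(ValueError):
    """One or more input rows failed validation; carries (row, message)."""

    def __init__(self, errors: List[Tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {r}: {m}" for r, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid record(s): {lines}{more}")


@dataclass(frozen=True)
class StudyConfig:
    """Run-wide configuration: rule thresholds, CI level, display rounding."""

    thresholds: Thresholds = DEFAULT_THRESHOLDS
    ci_level: float = 0.95
    percent_decimals: int = 1
    lr_decimals: int = 2

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        import tomllib
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        tcfg = raw.get("thresholds", {})
        thresholds = Thresholds(
            ratio_threshold=tcfg.get("ratio_threshold", 0.70),
            percent_threshold=tcfg.get("percent_threshold", 80.0),
            severity_edges=tuple(tcfg.get("severity_edges", (35.0, 50.0, 60.0, 70.0))),
            bd_pct=tcfg.get("bd_pct", 12.0),
            bd_abs_l=tcfg.get("bd_abs_l", 0.2),
        )
        return cls(thresholds=thresholds,
                   ci_level=raw.get("ci_level", 0.95),
                   percent_decimals=raw.get("percent_decimals", 1),
                   lr_decimals=raw.get("lr_decimals", 2))


def _load_frame(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".json", ".jsonl", ".ndjson"):
        return pd.read_json(path, lines=True, precise_float=True)
    return pd.read_csv(path)


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_records(path, mode: str = "volumes",
                 predictor: Optional[ReferencePredictor] = None
                 ) -> List[SpirometryRecord]:
    """Read and validate subject records from CSV or JSON-lines.

    ``mode="volumes"`` expects absolute litres plus predicted values
    (``RECORD_COLUMNS``); a registered ``predictor`` may supply missing
    predicted values from the anthropometrics.  ``mode="percent"`` expects
    percent-of-predicted indices directly (``PERCENT_COLUMNS``); such
    records carry no absolute post-bronchodilator volumes, so the
    reversibility test is not evaluable.

    Raises
    ------
    RecordValidationError
        Listing every malformed row with its (1-based) data row number.
    """
    df = _load_frame(path)
    if mode not in ("volumes", "percent"):
        raise ValueError(f"unknown mode: {mode!r}")
    required = (("subject_id", "sex", "age", "height", "weight",
                 "fvc_pre_L", "fev1_pre_L") if mode == "volumes"
                else PERCENT_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError([(0, f"missing required column(s): {missing}")])

    records: List[SpirometryRecord] = []
    errors: List[Tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            if mode == "percent":
                records.append(_record_from_percent(row))
            else:
                records.append(_record_from_volumes(row, predictor))
        except (InvalidRecordError, ValueError, TypeError, KeyError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise RecordValidationError(errors)
    log.info("read %d records from %s (mode=%s)", len(records), path, mode)
    return records


def _record_from_volumes(row: dict, predictor: Optional[ReferencePredictor]
                         ) -> SpirometryRecord:
    fvc_pred = _opt(row.get("fvc_pred_L"))
    fev1_pred = _opt(row.get("fev1_pred_L"))
    if (fvc_pred is None or fev1_pred is None) and predictor is not None:
        fvc_pred, fev1_pred = predictor(str(row["sex"]), float(row["age"]),
                                        float(row["height"]), float(row["weight"]))
    if fvc_pred is None or fev1_pred is None:
        raise InvalidRecordError("predicted values missing and no reference "
                                 "predictor registered", "fvc_pred_L",
                                 str(row.get("subject_id")))
    return SpirometryRecord(
        subject_id=str(row["subject_id"]), sex=str(row["sex"]),
        age=float(row["age"]), height=float(row["height"]),
        weight=float(row["weight"]),
        fvc_pre_L=float(row["fvc_pre_L"]), fev1_pre_L=float(row["fev1_pre_L"]),
        fvc_pred_L=float(fvc_pred), fev1_pred_L=float(fev1_pred),
        fvc_post_L=_opt(row.get("fvc_post_L")),
        fev1_post_L=_opt(row.get("fev1_post_L")),
    )


def _record_from_percent(row: dict) -> SpirometryRecord:
    """Synthesise a volume-scale record from percent-of-predicted inputs.

    The derived indices of the returned record equal the given fvc_pct,
    fev1_pct and ratio exactly; absolute volumes are nominal.
    """
    fvc_pct = float(row["fvc_pct"])
    fev1_pct = float(row["fev1_pct"])
    ratio = float(row["ratio"])
    sid = str(row["subject_id"])
    if not (0.0 <= ratio <= 1.0):
        raise InvalidRecordError(f"ratio must be in [0, 1], got {ratio}",
                                 "ratio", sid)
    if fvc_pct <= 0 or fev1_pct <= 0:
        raise InvalidRecordError("percent-of-predicted values must be > 0",
                                 "fvc_pct", sid)
    return SpirometryRecord(
        subject_id=sid, sex=str(row.get("sex", "male")),
        age=float(row.get("age", 50.0)), height=float(row.get("height", 170.0)),
        weight=float(row.get("weight", 70.0)),
        fvc_pre_L=1.0, fev1_pre_L=ratio,
        fvc_pred_L=100.0 / fvc_pct, fev1_pred_L=100.0 * ratio / fev1_pct,
    )


def write_records(records: Sequence[SpirometryRecord], path) -> None:
    """Write records as CSV with the documented column layout."""
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in RECORD_COLUMNS})
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    """Read a rater-interpretation file: subject_id → pattern
    (and optionally severity, bd_test). Missing calls stay as NaN."""
    df = _load_frame(path)
    if "subject_id" not in df.columns or "pattern" not in df.columns:
        raise RecordValidationError(
            [(0, "calls file needs 'subject_id' and 'pattern' columns")])
    return df


def interpret_records(records: Sequence[SpirometryRecord],
                      thresholds: Thresholds = DEFAULT_THRESHOLDS
                      ) -> List[InterpretationReport]:
    return [interpret_record(r, thresholds) for r in records]


def reports_to_frame(reports: Sequence[InterpretationReport]) -> pd.DataFrame:
    """Flat one-row-per-subject summary of interpretation reports."""
    rows = []
    for rep in reports:
        d = rep.to_dict()
        ind = d.pop("indices")
        d.update({f"{k}": v for k, v in ind.items()})
        d["flags"] = ",".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def confusion_from_table(t: ContingencyTable) -> Confusion2x2:
    """View a (normal, impaired) contingency table (rows = test, cols =
    gold standard) as a 2×2 confusion of the test."""
    if tuple(t.categories) != ("normal", "impaired"):
        raise ValueError("expected categories ('normal', 'impaired'), got "
                         f"{t.categories}")
    c = t.counts
    return Confusion2x2(tp=int(c[1, 1]), fp=int(c[1, 0]),
                        fn=int(c[0, 1]), tn=int(c[0, 0]))


def _acc_cell(r: AccuracyResult) -> dict:
    def clean(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return None
        if isinstance(x, float) and math.isinf(x):
            return "inf"
        return x
    return {"estimate": clean(r.estimate), "ci_low": clean(r.ci_low),
            "ci_high": clean(r.ci_high), "ci_method": r.ci_method}


def validity_report(c: Confusion2x2, level: float = 0.95) -> dict:
    """All validity statistics of one 2×2 table, with method tags."""
    plr, nlr = likelihood_ratios(c, level)
    return {
        "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn, "n": c.n},
        "sensitivity": _acc_cell(sensitivity(c, level)),
        "specificity": _acc_cell(specificity(c, level)),
        "ppv": _acc_cell(ppv(c, level)),
        "npv": _acc_cell(npv(c, level)),
        "plr": _acc_cell(plr),
        "nlr": _acc_cell(nlr),
        "accuracy": _acc_cell(accuracy(c, level)),
        "auc": _acc_cell(binary_auc(c, level)),
    }


def kappa_report(k: KappaResult) -> dict:
    return {"kappa": k.kappa, "se": k.se, "ci_low": k.ci_low,
            "ci_high": k.ci_high, "po": k.po, "pe": k.pe, "n": k.n,
            "label": k.label, "ci_method": "wald_fleiss_cohen_everitt"}


def reproduce_study(level: float = 0.95) -> dict:
    """Recompute every statistic derivable from the published count fixtures.

    Returns a deterministic report bundle: validity statistics of the
    normal/impaired dichotomy against both pulmonologists, the multi-pattern
    kappas (3×3 and 4×4), and the dichotomous kappas.
    """
    fx = table_fixtures()
    bundle: Dict[str, dict] = {"ci_level": level, "validity": {},
                               "pattern_agreement": {}, "dichotomous_agreement": {}}
    for rater in ("rater1", "rater2"):
        c = confusion_from_table(fx[f"dichotomous_{rater}"])
        bundle["validity"][rater] = validity_report(c, level)
        bundle["dichotomous_agreement"][rater] = kappa_report(
            cohen_kappa(fx[f"dichotomous_{rater}"], level=level))
        bundle["pattern_agreement"][rater] = kappa_report(
            cohen_kappa(fx[f"pattern_{rater}"], level=level))
    return bundle


def bundle_json(bundle: dict) -> str:
    """Canonical JSON rendering (sorted keys) so repeated runs are
    byte-identical."""
    return json.dumps(bundle, indent=2, sort_keys=True, allow_nan=False)


def setup_logging(verbosity: int = 0) -> None:
    """Configure package logging; never alters computed outputs."""
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG)
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logging.getLogger("spirokit").setLevel(level)
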