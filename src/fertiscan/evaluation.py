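"""Evaluation of ranked crop predictions against a dominant-crop reference.

A record's top-1 prediction is compared with the district's dominant crop;
aggregating over records gives a confusion matrix and the usual per-class
precision / recall / F1 / support report, plus a separate top-k hit rate for
records whose dominant crop appears further down the ranking. The 0/0
quotients that arise for classes never predicted (or never present) are
defined as 0.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .suitability import _canon_index

__all__ = [
    "LabeledRecord",
    "ConfusionMatrix",
    "ClassMetrics",
    "ClassReport",
    "EvaluationResult",
    "top1_match",
    "confusion_matrix",
    "classification_report",
    "evaluate",
    "load_records",
    "load_reference_records",
    "load_crop_calendar",
]


@dataclass(frozen=True)
class LabeledRecord:
    """One evaluation row: district, true dominant crop, ranked predictions."""

    district: str
    dominant_crop: str
    predicted_crops: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predicted_crops:
            raise ValueError(f"{self.district}: predicted_crops must be non-empty")
        object.__setattr__(self, "predicted_crops", tuple(self.predicted_crops))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[true, predicted] over the union of observed labels."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (n_labels, n_labels) int, rows = true

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    match_count: int
    macro_f1: float
    micro_f1: float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: vars(m).copy() for c, m in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "match_count": self.match_count,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
        }


def top1_match(rec: LabeledRecord) -> int:
    """1 iff the rank-1 prediction equals the dominant crop."""
    return int(rec.predicted_crops[0] == rec.dominant_crop)


def confusion_matrix(records: list[LabeledRecord]) -> ConfusionMatrix:
    """Top-1 confusion matrix over the union of observed labels.

    Labels are ordered canonically (rule-engine crop order, unknown names
    alphabetically after).
    """
    if not records:
        raise ValueError("records must be non-empty")
    observed = {r.dominant_crop for r in records} | {
        r.predicted_crops[0] for r in records
    }
    labels = tuple(sorted(observed, key=_canon_index))
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for r in records:
        counts[index[r.dominant_crop], index[r.predicted_crops[0]]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def classification_report(cm: ConfusionMatrix) -> ClassReport:
    """Per-class precision, recall, F1 and support from a confusion matrix.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    f1 = 2 * precision * recall / (precision + recall); 0/0 is 0.0.
    """
    counts = cm.counts
    per_class = {}
    f1s = []
    for i, label in enumerate(cm.labels):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        per_class[label] = ClassMetrics(
            precision=precision, recall=recall, f1=f1, support=int(tp + fn)
        )
        f1s.append(f1)
    diag = int(np.trace(counts))
    total = cm.total()
    accuracy = _safe_div(diag, total)
    return ClassReport(
        per_class=per_class,
        accuracy=accuracy,
        match_count=diag,
        macro_f1=float(np.mean(f1s)),
        micro_f1=accuracy,  # micro-averaged F1 equals accuracy for single-label top-1
    )


@dataclass(frozen=True)
class EvaluationResult:
    report: ClassReport
    matrix: ConfusionMatrix
    matches: list[int]  # per-record top-1 match flags, input order
    topk_hit_rate: float
    k: int

    def to_dict(self) -> dict:
        return {
            "report": self.report.to_dict(),
            "labels": list(self.matrix.labels),
            "confusion": self.matrix.counts.tolist(),
            "matches": list(self.matches),
            "topk_hit_rate": self.topk_hit_rate,
            "k": self.k,
        }


def evaluate(records: list[LabeledRecord], k: int = 1) -> EvaluationResult:
    """Full evaluation: report, matrix, per-record matches, top-k hit rate.

    Accuracy always uses top-1; the hit rate additionally counts records
    whose dominant crop appears anywhere in the first ``k`` predictions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cm = confusion_matrix(records)
    report = classification_report(cm)
    matches = [top1_match(r) for r in records]
    hits = sum(
        1 for r in records if r.dominant_crop in r.predicted_crops[:k]
    )
    return EvaluationResult(
        report=report,
        matrix=cm,
        matches=matches,
        topk_hit_rate=hits / len(records),
        k=k,
    )


def _records_from_rows(rows: list[dict], source: str) -> list[LabeledRecord]:
    records = []
    for i, row in enumerate(rows):
        missing = [c for c in ("district", "dominant_crop", "predicted_crops") if c not in row]
        if missing:
            raise ValueError(f"{source}: record {i} missing columns {missing}")
        preds = row["predicted_crops"]
        if isinstance(preds, str):
            preds = [p.strip() for p in preds.split(";") if p.strip()]
        records.append(
            LabeledRecord(
                district=str(row["district"]),
                dominant_crop=str(row["dominant_crop"]),
                predicted_crops=tuple(preds),
            )
        )
    return records


def load_records(path: str | Path) -> list[LabeledRecord]:
    """Load labeled records from CSV (semicolon-separated ranking) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return _records_from_rows(rows, str(path))


def _data_path(name: str):
    return resources.files("fertiscan.data").joinpath(name)


def load_reference_records() -> list[LabeledRecord]:
    """The packaged 20-district dominant-vs-predicted reference table."""
    with resources.as_file(_data_path("table4_records.csv")) as p:
        return load_records(p)


def load_crop_calendar() -> pd.DataFrame:
    """The packaged Crop Weather Calendar (AICRPAM centre, crop) pairs."""
    with resources.as_file(_data_path("table2_cwc.csv")) as p:
        return pd.read_csv(p)
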