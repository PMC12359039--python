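"""Scoring of predicted badges against manual labels.

Computes the standard multi-class classification statistics used to
benchmark the automated badge predictor against human badge assignments:
the confusion matrix, overall accuracy (correct predictions over all
predictions), per-class precision/recall/F1 with support, the macro-average
F1 (unweighted mean over classes present in the truth labels) and the
weighted F1 (truth-support weighted), plus the collapsed binary
None-versus-Badged view.

Implemented with plain counting so that reports are cheap enough for
exhaustive enumeration in verification; the arithmetic follows the usual
conventions (F1 = 0 when precision + recall = 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .badge_engine import Badge, collapse_binary

#: canonical display order for known labels
_CLASS_ORDER = ["none", "bronze", "silver", "gold", "cannot_be_determined",
                "not_badged", "badged"]

UNDETERMINED = Badge.CANNOT_BE_DETERMINED.value


@dataclass(frozen=True)
class LabeledPrediction:
    item_id: str
    true_badge: str
    predicted_badge: str


@dataclass
class ClassStats:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvaluationReport:
    confusion: dict[str, dict[str, int]]  # truth class -> predicted class -> n
    accuracy: float
    per_class: dict[str, ClassStats]
    macro_f1: float
    weighted_f1: float
    n_items: int


def _ordered(labels: Iterable[str]) -> list[str]:
    labels = set(labels)
    known = [c for c in _CLASS_ORDER if c in labels]
    return known + sorted(labels - set(known))


def evaluate(predictions: Sequence[LabeledPrediction],
             classes: Sequence[str] | None = None,
             exclude_undetermined: bool = True) -> EvaluationReport:
    """Score predictions against truth labels.

    ``classes`` controls which classes enter the per-class table and the
    macro/weighted averages; by default these are the classes present in
    the truth labels (a class predicted but never true then contributes
    nothing to the averages, though it still appears in the confusion
    matrix). With ``exclude_undetermined`` (default), items whose truth or
    prediction is ``cannot_be_determined`` are dropped before scoring.
    """
    items = [(p.true_badge, p.predicted_badge) for p in predictions]
    if exclude_undetermined:
        items = [(t, p) for t, p in items
                 if UNDETERMINED not in (t, p)]
    if not items:
        raise ValueError("no predictions to evaluate (after exclusions)")

    truths = [t for t, _ in items]
    if classes is None:
        classes = _ordered(truths)
    matrix_classes = _ordered(set(classes) | {lab for tp in items for lab in tp})

    confusion = {t: {p: 0 for p in matrix_classes} for t in matrix_classes}
    for t, p in items:
        confusion[t][p] += 1

    n = len(items)
    accuracy = sum(confusion[c][c] for c in matrix_classes) / n

    per_class: dict[str, ClassStats] = {}
    for c in classes:
        tp = confusion[c][c]
        fp = sum(confusion[t][c] for t in matrix_classes if t != c)
        fn = sum(confusion[c][p] for p in matrix_classes if p != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) \
            if precision + recall else 0.0
        per_class[c] = ClassStats(precision, recall, f1, support=tp + fn)

    macro_f1 = sum(s.f1 for s in per_class.values()) / len(per_class)
    total_support = sum(s.support for s in per_class.values())
    weighted_f1 = (sum(s.f1 * s.support for s in per_class.values())
                   / total_support) if total_support else 0.0
    return EvaluationReport(confusion, accuracy, per_class,
                            macro_f1, weighted_f1, n)


def evaluate_binary(predictions: Sequence[LabeledPrediction],
                    exclude_undetermined: bool = True) -> EvaluationReport:
    """Collapse truth and predictions to None-versus-Badged, then score.

    With ``exclude_undetermined`` (default) undetermined items are dropped
    first; otherwise they collapse to not-badged.
    """
    items = list(predictions)
    if exclude_undetermined:
        items = [p for p in items
                 if UNDETERMINED not in (p.true_badge, p.predicted_badge)]
    collapsed = [
        LabeledPrediction(p.item_id,
                          collapse_binary(p.true_badge).value,
                          collapse_binary(p.predicted_badge).value)
        for p in items
    ]
    return evaluate(collapsed, exclude_undetermined=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> list[LabeledPrediction]:
    """Read labeled predictions from a CSV with header columns
    ``true,predicted`` (an optional leading ``item_id`` column is used when
    present)."""
    out: list[LabeledPrediction] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                not {"true", "predicted"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns 'true' and 'predicted'")
        for i, row in enumerate(reader):
            out.append(LabeledPrediction(row.get("item_id") or str(i),
                                         row["true"].strip(),
                                         row["predicted"].strip()))
    return out


def report_rows(report: EvaluationReport, view: str) -> list[dict]:
    """Flatten a report to long-format rows for CSV output."""
    rows = [
        {"view": view, "scope": "overall", "name": "accuracy",
         "value": report.accuracy},
        {"view": view, "scope": "overall", "name": "macro_f1",
         "value": report.macro_f1},
        {"view": view, "scope": "overall", "name": "weighted_f1",
         "value": report.weighted_f1},
        {"view": view, "scope": "overall", "name": "n_items",
         "value": report.n_items},
    ]
    for cls, stats in report.per_class.items():
        for name in ("precision", "recall", "f1", "support"):
            rows.append({"view": view, "scope": cls, "name": name,
                         "value": getattr(stats, name)})
    return rows


def summarize(report: EvaluationReport) -> str:
    lines = [f"n={report.n_items}  accuracy={report.accuracy:.3f}  "
             f"macro_f1={report.macro_f1:.3f}  weighted_f1={report.weighted_f1:.3f}"]
    for cls, s in report.per_class.items():
        lines.append(f"  {cls:<22} P={s.precision:.3f} R={s.recall:.3f} "
                     f"F1={s.f1:.3f} support={s.support}")
    return "\n".join(lines)
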