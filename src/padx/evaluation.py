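"""Scoring extracted elements against gold annotations.

Matching is exact (element, value) string agreement with multiset semantics,
evaluated text by text over a parallel gold/predicted corpus: a predicted
mention that matches a gold mention is a true positive, an unmatched
prediction a false positive, an unmatched gold mention a false negative.

Metrics follow the printed-table convention: precision ``TP/(TP+FP)`` and
recall ``TP/(TP+FN)`` are expressed as percentages rounded half-up to one
decimal, and F1 ``2PR/(P+R)`` is computed *from the already-rounded* P and R
before being rounded itself — the published cells only reproduce under this
rounded-inputs convention. Metrics with an empty denominator are reported as
not-applicable (None), never silently as 0 or 100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from ._text import nfc, percentage
from .extraction import ELEMENT_TYPES, ElementMention, ExtractionResult


class AlignmentError(ValueError):
    """Gold and predicted corpora are not parallel (length or text mismatch)."""


@dataclass
class GoldAnnotation:
    """Human-labeled mentions for one diagnosis text (the gold standard)."""

    source_text: str
    mentions: list[ElementMention] = field(default_factory=list)


@dataclass
class EvalCounts:
    element: str
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class ElementMetrics:
    """P/R/F1 percentages at one decimal; None where undefined."""

    element: str
    precision_pct: Optional[float]
    recall_pct: Optional[float]
    f1_pct: Optional[float]


@dataclass(frozen=True)
class Discrepancy:
    """One unmatched mention, for the human review loop."""

    text: str
    element: str
    gold_value: Optional[str]
    predicted_value: Optional[str]
    kind: str  # FP | FN


def _check_alignment(
    gold: Sequence[GoldAnnotation], predicted: Sequence[ExtractionResult]
) -> None:
    if len(gold) != len(predicted):
        raise AlignmentError(
            f"gold has {len(gold)} texts but predictions have {len(predicted)}"
        )
    for idx, (g, p) in enumerate(zip(gold, predicted)):
        if nfc(g.source_text) != nfc(p.source_text):
            raise AlignmentError(f"text mismatch at index {idx}")


def _value_counter(mentions: Sequence[ElementMention], element: str) -> Counter:
    return Counter(m.value for m in mentions if m.element == element)


def compare_annotations(
    gold: Sequence[GoldAnnotation], predicted: Sequence[ExtractionResult]
) -> dict[str, EvalCounts]:
    """Per-element TP/FP/FN over a parallel corpus (multiset value matching)."""
    _check_alignment(gold, predicted)
    counts = {element: EvalCounts(element) for element in ELEMENT_TYPES}
    for g, p in zip(gold, predicted):
        for element in ELEMENT_TYPES:
            gold_values = _value_counter(g.mentions, element)
            pred_values = _value_counter(p.mentions, element)
            matched = sum((gold_values & pred_values).values())
            counts[element].tp += matched
            counts[element].fp += sum(pred_values.values()) - matched
            counts[element].fn += sum(gold_values.values()) - matched
    return counts


def compute_metrics(counts: EvalCounts) -> ElementMetrics:
    """P, R and F1 from raw counts under the rounded-inputs F1 convention."""
    precision = percentage(counts.tp, counts.tp + counts.fp)
    recall = percentage(counts.tp, counts.tp + counts.fn)
    f1: Optional[float] = None
    if precision is not None and recall is not None:
        if precision + recall > 0:
            p = Decimal(str(precision))
            r = Decimal(str(recall))
            f1 = float((2 * p * r / (p + r)).quantize(Decimal("0.1"), ROUND_HALF_UP))
        else:
            f1 = 0.0
    return ElementMetrics(counts.element, precision, recall, f1)


def metrics_by_element(counts: dict[str, EvalCounts]) -> dict[str, ElementMetrics]:
    return {element: compute_metrics(c) for element, c in counts.items()}


def metrics_table(counts: dict[str, EvalCounts]) -> pd.DataFrame:
    """Tabular layout: element, TP, FP, FN, P, R, F1 (one row per element)."""
    rows = []
    for element in ELEMENT_TYPES:
        c = counts.get(element, EvalCounts(element))
        m = compute_metrics(c)
        rows.append(
            {
                "element": element,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "precision_pct": m.precision_pct,
                "recall_pct": m.recall_pct,
                "f1_pct": m.f1_pct,
            }
        )
    return pd.DataFrame(rows)


def error_report(
    gold: Sequence[GoldAnnotation], predicted: Sequence[ExtractionResult]
) -> list[Discrepancy]:
    """One record per unmatched mention; empty when extraction is perfect."""
    _check_alignment(gold, predicted)
    report: list[Discrepancy] = []
    for g, p in zip(gold, predicted):
        for element in ELEMENT_TYPES:
            gold_values = _value_counter(g.mentions, element)
            pred_values = _value_counter(p.mentions, element)
            for value, n in sorted((gold_values - pred_values).items()):
                report.extend(
                    Discrepancy(g.source_text, element, value, None, "FN") for _ in range(n)
                )
            for value, n in sorted((pred_values - gold_values).items()):
                report.extend(
                    Discrepancy(g.source_text, element, None, value, "FP") for _ in range(n)
                )
    return report
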