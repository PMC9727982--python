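"""File formats: corpus and gold JSONL, result JSONL, CSV tables, GraphML.

All text I/O is UTF-8. Offsets in serialized mentions are 0-based half-open
on the NFC text. CSV files carry a header row and RFC-4180 quoting (pandas
defaults). The nested-entity serialization uses the field names
``word`` / ``entity_class`` / ``value``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import pandas as pd

from ._text import nfc
from .analytics import DiagnosisRecord, DiversityReport, KnowledgeGraphSpec, MissingnessTable
from .evaluation import (
    Discrepancy,
    ElementMetrics,
    EvalCounts,
    GoldAnnotation,
    metrics_table,
)
from .extraction import ElementMention, ExtractionResult, NestedEntity
from .segmenter import Span

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """A malformed corpus/gold line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_corpus(path: PathLike) -> list[DiagnosisRecord]:
    """Read diagnosis records from JSONL with fields ``text`` (required),
    ``seq`` (default 1), ``department`` and ``id`` (autogenerated)."""
    records: list[DiagnosisRecord] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(lineno, f"invalid JSON: {exc}") from None
            if not isinstance(payload, dict) or "text" not in payload:
                raise CorpusFormatError(lineno, "record must be an object with a 'text' field")
            seq = payload.get("seq", 1)
            if seq not in (1, 2, 3):
                raise CorpusFormatError(lineno, f"seq must be 1, 2 or 3, got {seq!r}")
            records.append(
                DiagnosisRecord(
                    text=nfc(str(payload["text"])),
                    seq=seq,
                    department=payload.get("department"),
                    record_id=str(payload.get("id", f"L{lineno:05d}")),
                )
            )
    return records


def write_corpus(records: Sequence[DiagnosisRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            payload = {"text": record.text, "seq": record.seq, "id": record.record_id}
            if record.department is not None:
                payload["department"] = record.department
            handle.write(json.dumps(payload, ensure_ascii=False) + "\n")


def _mentions_from_payload(payload: dict, lineno: int) -> list[ElementMention]:
    mentions = []
    for item in payload.get("mentions", []):
        try:
            mentions.append(
                ElementMention(
                    item["element"], item["value"], Span(item["start"], item["end"])
                )
            )
        except (KeyError, ValueError) as exc:
            raise CorpusFormatError(lineno, f"bad mention: {exc}") from None
    return mentions


def read_gold(path: PathLike) -> list[GoldAnnotation]:
    """Gold annotations as JSONL: ``{"text": ..., "mentions": [...]}``."""
    annotations: list[GoldAnnotation] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            payload = json.loads(line)
            annotations.append(
                GoldAnnotation(nfc(payload["text"]), _mentions_from_payload(payload, lineno))
            )
    return annotations


def write_gold(annotations: Sequence[GoldAnnotation], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for ann in annotations:
            payload = {
                "text": ann.source_text,
                "mentions": [
                    {
                        "element": m.element,
                        "value": m.value,
                        "start": m.span.start,
                        "end": m.span.end,
                    }
                    for m in ann.mentions
                ],
            }
            handle.write(json.dumps(payload, ensure_ascii=False) + "\n")


def read_extractions(path: PathLike) -> list[ExtractionResult]:
    results: list[ExtractionResult] = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            payload = json.loads(line)
            results.append(
                ExtractionResult(nfc(payload["text"]), _mentions_from_payload(payload, lineno))
            )
    return results


def write_extractions(
    results: Sequence[ExtractionResult],
    path: PathLike,
    entities: Optional[Sequence[Sequence[NestedEntity]]] = None,
) -> None:
    """Write extraction results as JSONL; optionally include the nested-entity
    trees (``word``/``entity_class``/``value``) alongside the mentions."""
    with open(path, "w", encoding="utf-8") as handle:
        for idx, result in enumerate(results):
            payload = result.to_dict()
            if entities is not None:
                payload["entities"] = [e.to_dict() for e in entities[idx]]
            handle.write(json.dumps(payload, ensure_ascii=False) + "\n")


def write_metrics_csv(counts: dict[str, EvalCounts], path: PathLike) -> None:
    metrics_table(counts).to_csv(path, index=False)


def read_metrics_csv(path: PathLike) -> dict[str, ElementMetrics]:
    frame = pd.read_csv(path)
    out: dict[str, ElementMetrics] = {}
    for row in frame.itertuples():
        out[row.element] = ElementMetrics(
            row.element,
            None if pd.isna(row.precision_pct) else float(row.precision_pct),
            None if pd.isna(row.recall_pct) else float(row.recall_pct),
            None if pd.isna(row.f1_pct) else float(row.f1_pct),
        )
    return out


def write_error_report(report: Sequence[Discrepancy], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for item in report:
            handle.write(
                json.dumps(
                    {
                        "text": item.text,
                        "element": item.element,
                        "gold_value": item.gold_value,
                        "predicted_value": item.predicted_value,
                        "kind": item.kind,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_graph(spec: KnowledgeGraphSpec, outdir: PathLike, stem: str = "graph") -> None:
    """Export the knowledge graph as GraphML and as plain node/edge JSON."""
    outdir = Path(outdir)
    nx.write_graphml(spec.to_networkx(), outdir / f"{stem}.graphml")
    (outdir / f"{stem}.json").write_text(
        json.dumps({"nodes": spec.nodes, "edges": spec.edges}, ensure_ascii=False, indent=2),
        encoding="utf-8",
    )


def write_outputs(
    results: Sequence[ExtractionResult],
    counts: Optional[dict[str, EvalCounts]] = None,
    analytics: Optional[dict] = None,
    outdir: PathLike = ".",
    entities: Optional[Sequence[Sequence[NestedEntity]]] = None,
) -> None:
    """Write the standard output bundle into *outdir* (created if absent).

    ``analytics`` may hold any of ``diversity`` (:class:`DiversityReport`),
    ``patterns`` (DataFrame), ``missingness`` (:class:`MissingnessTable`),
    ``unique_statements`` (DataFrame) and ``graph``
    (:class:`KnowledgeGraphSpec`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_extractions(results, outdir / "extractions.jsonl", entities)
    if counts is not None:
        write_metrics_csv(counts, outdir / "metrics.csv")
    analytics = analytics or {}
    diversity = analytics.get("diversity")
    if isinstance(diversity, DiversityReport):
        diversity.to_frame().to_csv(outdir / "diversity.csv", index=False)
    patterns = analytics.get("patterns")
    if patterns is not None:
        patterns.to_csv(outdir / "patterns.csv", index=False)
    missingness = analytics.get("missingness")
    if isinstance(missingness, MissingnessTable):
        missingness.frame.to_csv(outdir / "missingness.csv", index=False)
    unique = analytics.get("unique_statements")
    if unique is not None:
        unique.to_csv(outdir / "unique_statements.csv", index=False)
    graph = analytics.get("graph")
    if isinstance(graph, KnowledgeGraphSpec):
        write_graph(graph, outdir)
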