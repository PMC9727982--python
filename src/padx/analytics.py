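"""Corpus-level descriptive analyses of diagnosis statements.

Covers the real-world profiling side of the tool: statement deduplication,
per-element frequency and expression diversity, combination-pattern
distribution, missing-element comparison between principal (sequence 1) and
other (sequence 2-3) diagnoses with a Pearson chi-square test, and a
hub-and-spoke knowledge-graph export (root concept → element types →
observed values).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from ._text import nfc, percentage
from .extraction import ELEMENT_TYPES, ExtractionResult

logger = logging.getLogger(__name__)

DEFAULT_ROOT_LABEL = "pituitary adenoma"

#: Elements whose absence is reported by default (the basic descriptors).
DEFAULT_REQUIRED_ELEMENTS = ("tumor_location", "endocrine_status", "tumor_size")


@dataclass
class DiagnosisRecord:
    """One discharge-diagnosis record: free text plus its sequence number
    (1 = principal diagnosis, 2-3 = other diagnoses)."""

    text: str
    seq: int = 1
    department: Optional[str] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.seq not in (1, 2, 3):
            raise ValueError(f"diagnosis sequence must be 1, 2 or 3, got {self.seq}")


def normalize_statement(text: str) -> str:
    """NFC, trimmed, internal whitespace collapsed — the dedup equality key."""
    return re.sub(r"\s+", " ", nfc(text).strip())


def dedupe_statements(records: Sequence[DiagnosisRecord]) -> pd.DataFrame:
    """Unique statements with occurrence counts (counts sum to the input size),
    sorted by count descending then statement."""
    counts: dict[str, int] = {}
    for record in records:
        key = normalize_statement(record.text)
        counts[key] = counts.get(key, 0) + 1
    frame = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["statement", "count"],
    )
    return frame


@dataclass
class DiversityReport:
    """Per element: extraction frequency and number of distinct expressions.

    ``frequency`` counts mentions (so a bilateral Knosp statement counts
    twice) unless ``count_mode='text'``; ``distinct_variants`` counts unique
    mention values (``diversity_mode='value'``, the default) or unique
    statements containing the element (``'text'``).
    """

    frequency: dict[str, int] = field(default_factory=dict)
    distinct_variants: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element": element,
                "frequency": self.frequency.get(element, 0),
                "distinct_variants": self.distinct_variants.get(element, 0),
            }
            for element in ELEMENT_TYPES
        ]
        return pd.DataFrame(rows)


def frequency_and_diversity(
    results: Sequence[ExtractionResult],
    diversity_mode: str = "value",
    count_mode: str = "mention",
) -> DiversityReport:
    """Extraction frequency and expression diversity per element."""
    if diversity_mode not in ("value", "text"):
        raise ValueError(f"unknown diversity_mode: {diversity_mode!r}")
    if count_mode not in ("mention", "text"):
        raise ValueError(f"unknown count_mode: {count_mode!r}")
    frequency = {element: 0 for element in ELEMENT_TYPES}
    variants: dict[str, set[str]] = {element: set() for element in ELEMENT_TYPES}
    for result in results:
        present = result.elements
        for element in ELEMENT_TYPES:
            mentions = result.for_element(element)
            if count_mode == "mention":
                frequency[element] += len(mentions)
            elif element in present:
                frequency[element] += 1
            if diversity_mode == "value":
                variants[element].update(m.value for m in mentions)
            elif element in present:
                variants[element].add(normalize_statement(result.source_text))
    return DiversityReport(
        frequency=frequency,
        distinct_variants={el: len(v) for el, v in variants.items()},
    )


def pattern_key(elements: set[str]) -> str:
    """Canonical order-insensitive key, elements joined by '+' in table order."""
    return "+".join(el for el in ELEMENT_TYPES if el in elements)


def combination_patterns(
    results: Sequence[ExtractionResult], denominator: str = "all"
) -> pd.DataFrame:
    """Distribution of element-combination patterns, sorted by count.

    One pattern per text (the set of element types present). Percentages use
    all texts as denominator (``denominator='all'``) or only texts with at
    least one mention (``'nonempty'``); rounded half-up to one decimal.
    """
    if denominator not in ("all", "nonempty"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    counts: dict[str, int] = {}
    nonempty = 0
    for result in results:
        elements = result.elements
        if not elements:
            continue
        nonempty += 1
        key = pattern_key(elements)
        counts[key] = counts.get(key, 0) + 1
    den = len(results) if denominator == "all" else nonempty
    rows = [
        {
            "pattern": key,
            "n_elements": key.count("+") + 1 if key else 0,
            "count": count,
            "pct": percentage(count, den),
        }
        for key, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pattern", "n_elements", "count", "pct"])


def chi_square_2x2(table: Sequence[Sequence[int]]) -> Optional[float]:
    """Two-sided p of a Pearson chi-square test without continuity correction;
    None (with a warning) for degenerate tables with a zero margin."""
    frame = [[int(x) for x in row] for row in table]
    row_sums = [sum(row) for row in frame]
    col_sums = [frame[0][j] + frame[1][j] for j in range(2)]
    if min(row_sums) == 0 or min(col_sums) == 0:
        logger.warning("degenerate 2x2 table, chi-square skipped: %r", frame)
        return None
    result = stats.chi2_contingency(frame, correction=False)
    return float(result.pvalue)


@dataclass
class MissingnessTable:
    """Per element and stratum: missing count, denominator and percentage,
    plus the principal-vs-other chi-square p-value."""

    frame: pd.DataFrame

    def row(self, element: str) -> dict:
        match = self.frame[self.frame["element"] == element]
        if match.empty:
            raise KeyError(element)
        return match.iloc[0].to_dict()


def missingness_analysis(
    records: Sequence[DiagnosisRecord],
    results: Sequence[ExtractionResult],
    required_elements: Sequence[str] = DEFAULT_REQUIRED_ELEMENTS,
) -> MissingnessTable:
    """Element loss by diagnosis type. A text misses an element iff it has no
    mention of it; strata are all texts, principal (seq 1) and other (seq
    2-3). The p-value tests missing/present × principal/other independence."""
    if len(records) != len(results):
        raise ValueError("records and extraction results must be parallel")
    rows = []
    principal = [res for rec, res in zip(records, results) if rec.seq == 1]
    other = [res for rec, res in zip(records, results) if rec.seq != 1]
    for element in required_elements:
        miss_principal = sum(1 for res in principal if element not in res.elements)
        miss_other = sum(1 for res in other if element not in res.elements)
        miss_all = miss_principal + miss_other
        p_value = None
        if principal and other:
            p_value = chi_square_2x2(
                [
                    [miss_principal, len(principal) - miss_principal],
                    [miss_other, len(other) - miss_other],
                ]
            )
        rows.append(
            {
                "element": element,
                "missing_all": miss_all,
                "n_all": len(records),
                "pct_all": percentage(miss_all, len(records)),
                "missing_principal": miss_principal,
                "n_principal": len(principal),
                "pct_principal": percentage(miss_principal, len(principal)),
                "missing_other": miss_other,
                "n_other": len(other),
                "pct_other": percentage(miss_other, len(other)),
                "p_value": p_value,
            }
        )
    return MissingnessTable(pd.DataFrame(rows))


@dataclass
class KnowledgeGraphSpec:
    """Hub-and-spoke graph: root concept → element types → observed values."""

    nodes: list[dict]
    edges: list[dict]

    def to_networkx(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for node in self.nodes:
            graph.add_node(node["id"], kind=node["kind"], label=node["label"])
        for edge in self.edges:
            graph.add_edge(edge["source"], edge["target"])
        return graph


def build_knowledge_graph(
    results: Sequence[ExtractionResult], root_label: str = DEFAULT_ROOT_LABEL
) -> KnowledgeGraphSpec:
    """Deterministic knowledge-graph spec of all extracted element values.

    All ten element dimensions that occur in the corpus are kept as explicit
    element nodes around the root; value nodes are deduplicated per
    (element, value). Empty corpora give a root-only graph.
    """
    values: dict[str, set[str]] = {}
    for result in results:
        for mention in result.mentions:
            values.setdefault(mention.element, set()).add(mention.value)
    nodes = [{"id": "root", "kind": "root", "label": root_label}]
    edges = []
    for element in ELEMENT_TYPES:
        if element not in values:
            continue
        element_id = f"element:{element}"
        nodes.append({"id": element_id, "kind": "element", "label": element})
        edges.append({"source": "root", "target": element_id})
        for value in sorted(values[element]):
            value_id = f"value:{element}:{value}"
            nodes.append({"id": value_id, "kind": "value", "label": value})
            edges.append({"source": element_id, "target": value_id})
    return KnowledgeGraphSpec(nodes=nodes, edges=edges)
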