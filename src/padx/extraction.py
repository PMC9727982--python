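"""Nested (multilevel) entity extraction and diagnostic-element matching.

A discharge diagnosis for a pituitary adenoma packs several information
dimensions into one compound phrase ("复发难治性侵袭性GH分泌型垂体大腺瘤（左侧
Knosp分级3级）"). After coarse segmentation, compound tokens are recursively
re-segmented into nested sub-entities (multilevel segmentation), and tokens
and sub-entities are mapped onto ten diagnostic elements by a declarative
rule set. Knosp grades — lateralized, range-valued cavernous-sinus invasion
grades 0-4 — get a dedicated parser.

Every extracted mention is a verbatim substring of the (NFC) source text,
located by a 0-based half-open span.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from ._text import is_break_char, nfc
from .lexicon import PrefixLexicon
from .segmenter import HmmParams, Span, Token, _max_prob_path, _scan_words, segment

logger = logging.getLogger(__name__)

#: The ten diagnostic elements, in canonical (reporting) order.
ELEMENT_TYPES: tuple[str, ...] = (
    "tumor_recurrence",
    "tumor_location",
    "invasiveness",
    "endocrine_status",
    "tumor_size",
    "histopathology",
    "knosp_grade",
    "residual_tumor",
    "diagnostic_confirmation",
    "refractoriness",
)

_ELEMENT_ORDER = {name: idx for idx, name in enumerate(ELEMENT_TYPES)}

#: Characters that may separate the parts of a compound without being part
#: of any sub-entity (plus whitespace).
CONNECTOR_CHARS = "/-–."

_CONNECTOR_SPLIT_RE = re.compile(r"[/\-–.\s]+")

DEFAULT_DEPTH_CAP = 3


@dataclass
class NestedEntity:
    """A (possibly compound) entity; ``children`` are its sub-entities.

    Concatenating the children's words reproduces the parent word up to
    connector characters. Serializes to ``{"word", "entity_class", "value"}``.
    """

    word: str
    entity_class: str
    children: list["NestedEntity"] = field(default_factory=list)
    span: Optional[Span] = None

    def walk(self) -> Iterator["NestedEntity"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(child.depth() for child in self.children)

    def to_dict(self) -> dict:
        payload: dict = {"word": self.word, "entity_class": self.entity_class}
        if self.children:
            payload["value"] = [child.to_dict() for child in self.children]
        return payload


@dataclass(frozen=True)
class ElementMention:
    """One extracted value of one element; ``value`` re-slices from the text."""

    element: str
    value: str
    span: Span

    def __post_init__(self) -> None:
        if self.element not in _ELEMENT_ORDER:
            raise ValueError(f"unknown element type: {self.element!r}")


@dataclass(frozen=True)
class KnospMention:
    """A parsed Knosp expression: side, grade range (0-4) and verbatim text."""

    side: str  # left | right | unspecified
    grade_low: int
    grade_high: int
    raw: str
    span: Span

    def __post_init__(self) -> None:
        if not (0 <= self.grade_low <= self.grade_high <= 4):
            raise ValueError(f"Knosp grades out of range: {self.grade_low}-{self.grade_high}")


@dataclass
class MatchRule:
    """One element-matching rule.

    kind ``literal``: the (casefolded) surface of a token or sub-entity;
    kind ``class``: the entity class of a token or sub-entity;
    kind ``regex``: a pattern applied to the full source text (multiword
    English phrases, hormone combinations). Higher priority wins; within a
    priority, the longer match wins.
    """

    element: str
    kind: str
    pattern: str
    priority: int = 10

    def __post_init__(self) -> None:
        if self.element not in _ELEMENT_ORDER:
            raise ValueError(f"unknown element type: {self.element!r}")
        if self.kind not in ("literal", "class", "regex"):
            raise ValueError(f"unknown rule kind: {self.kind!r}")
        if self.kind == "literal":
            self.pattern = nfc(self.pattern).casefold()
        if self.kind == "regex":
            self._compiled = re.compile(self.pattern, re.IGNORECASE)


@dataclass
class ExtractionResult:
    """Per-text mapping from the ten elements to extracted mentions."""

    source_text: str
    mentions: list[ElementMention] = field(default_factory=list)

    def values(self, element: str) -> list[str]:
        return [m.value for m in self.mentions if m.element == element]

    def for_element(self, element: str) -> list[ElementMention]:
        return [m for m in self.mentions if m.element == element]

    @property
    def elements(self) -> set[str]:
        return {m.element for m in self.mentions}

    def to_dict(self) -> dict:
        return {
            "text": self.source_text,
            "mentions": [
                {
                    "element": m.element,
                    "value": m.value,
                    "start": m.span.start,
                    "end": m.span.end,
                }
                for m in self.mentions
            ],
        }


# ---------------------------------------------------------------------------
# Multilevel segmentation
# ---------------------------------------------------------------------------


def _decompose_chunk(
    chunk: str, lexicon: PrefixLexicon
) -> Optional[list[tuple[str, int, int]]]:
    """Split *chunk* into >=2 dictionary words by max-probability DP, with the
    full-span word (the chunk itself) excluded. None if no such split: the
    best path must consist purely of dictionary words."""
    n = len(chunk)
    if n < 2:
        return None
    units = [(Span(i, i + 1), "char") for i in range(n)]
    edges, word_freq = _scan_words(chunk, units, lexicon)
    # The chunk itself must not re-emerge as a single word.
    word_freq.pop((0, n), None)
    edges[0] = [j for j in edges[0] if j != n]
    path = _max_prob_path(n, edges, word_freq, lexicon.total_frequency)
    if len(path) < 2 or any((i, j) not in word_freq for i, j in path):
        return None
    return [(chunk[i:j], i, j) for i, j in path]


def multilevel_segment(
    token: Token, lexicon: PrefixLexicon, depth_cap: int = DEFAULT_DEPTH_CAP
) -> NestedEntity:
    """Recursively re-segment a compound token into nested sub-entities.

    A surface decomposes when, after removing connector characters, it splits
    into two or more dictionary words; decomposition recurses on each part
    until atomic or *depth_cap* levels deep. Atomic tokens come back as
    leaves.
    """
    if depth_cap < 1:
        raise ValueError("depth_cap must be >= 1")
    root = NestedEntity(token.surface, token.entity_class, [], token.span)
    root.children = _split_entity(token.surface, token.span.start, lexicon, depth_cap - 1)
    return root


def _split_entity(
    surface: str, base: int, lexicon: PrefixLexicon, depth_left: int
) -> list[NestedEntity]:
    if depth_left < 1:
        return []
    chunks: list[tuple[str, int]] = []
    pos = 0
    for match in _CONNECTOR_SPLIT_RE.finditer(surface):
        if match.start() > pos:
            chunks.append((surface[pos : match.start()], pos))
        pos = match.end()
    if pos < len(surface):
        chunks.append((surface[pos:], pos))

    if len(chunks) > 1:
        children = []
        for chunk, offset in chunks:
            entry = lexicon.lookup(chunk)
            cls = entry.entity_class if entry else "unknown"
            node = NestedEntity(chunk, cls, [], Span(base + offset, base + offset + len(chunk)))
            node.children = _split_entity(chunk, base + offset, lexicon, depth_left - 1)
            children.append(node)
        return children

    if not chunks:
        return []
    chunk, offset = chunks[0]
    parts = _decompose_chunk(chunk, lexicon)
    if parts is None:
        return []
    children = []
    for word, i, j in parts:
        entry = lexicon.lookup(word)
        cls = entry.entity_class if entry else "unknown"
        node = NestedEntity(word, cls, [], Span(base + offset + i, base + offset + j))
        node.children = _split_entity(word, base + offset + i, lexicon, depth_left - 1)
        children.append(node)
    return children


# ---------------------------------------------------------------------------
# Knosp grade parsing
# ---------------------------------------------------------------------------

KNOSP_RE = re.compile(
    r"(?:(?P<pre>left|right|左|右|双)\s*(?:side|侧)?\s*)?"
    r"(?<![A-Za-z])Knosp"
    r"\s*(?:grade|分级|分期)?\s*"
    r"(?P<g1>\d)(?:\s*[–\-—~～]\s*(?P<g2>\d))?"
    r"\s*(?:级|grade)?"
    r"(?:\s*on\s+the\s+(?P<post>left|right)(?:\s+side)?)?",
    re.IGNORECASE,
)

_SIDE_MAP = {"left": "left", "右": "right", "right": "right", "左": "left", "双": "unspecified"}


def parse_knosp(text: str) -> list[KnospMention]:
    """All Knosp expressions in *text* (verbatim, with side and grade range).

    Sides are recognized in Chinese (左/右/双侧) and English (left/right,
    before or after the grade); ranges accept ``– - — ~ ～``. Grades outside
    0-4 are rejected with a warning rather than an exception.
    """
    text = nfc(text)
    mentions: list[KnospMention] = []
    for match in KNOSP_RE.finditer(text):
        g1 = int(match.group("g1"))
        g2 = int(match.group("g2")) if match.group("g2") else g1
        low, high = min(g1, g2), max(g1, g2)
        if high > 4:
            logger.warning("Knosp grade outside 0-4 rejected: %r", match.group(0))
            continue
        side = "unspecified"
        pre, post = match.group("pre"), match.group("post")
        if pre:
            side = _SIDE_MAP.get(pre.casefold(), "unspecified")
        elif post:
            side = _SIDE_MAP.get(post.casefold(), "unspecified")
        mentions.append(
            KnospMention(
                side=side,
                grade_low=low,
                grade_high=high,
                raw=match.group(0),
                span=Span(match.start(), match.end()),
            )
        )
    return mentions


# ---------------------------------------------------------------------------
# Rule loading and element matching
# ---------------------------------------------------------------------------

KNOSP_PRIORITY = 100


def load_rules(source: Union[str, Path]) -> list[MatchRule]:
    """Load a declarative ruleset from a JSON file.

    Each item holds ``element``, ``kind``, ``priority`` and either ``values``
    (a list of literal surfaces, expanded into one rule each) or ``pattern``.
    """
    payload = json.loads(Path(source).read_text("utf-8"))
    rules: list[MatchRule] = []
    for item in payload["rules"]:
        priority = int(item.get("priority", 10))
        if "values" in item:
            for value in item["values"]:
                rules.append(MatchRule(item["element"], item["kind"], value, priority))
        else:
            rules.append(MatchRule(item["element"], item["kind"], item["pattern"], priority))
    return rules


_DEFAULT_RULES: Optional[list[MatchRule]] = None


def default_rules() -> list[MatchRule]:
    """The packaged pituitary-adenoma ruleset covering all ten elements."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        with resources.as_file(resources.files("padx.data").joinpath("rules.json")) as path:
            _DEFAULT_RULES = load_rules(path)
    return list(_DEFAULT_RULES)


@dataclass(frozen=True)
class _Candidate:
    priority: int
    span: Span
    mention: ElementMention

    def sort_key(self) -> tuple:
        return (
            -self.priority,
            -(self.span.end - self.span.start),
            self.span.start,
            _ELEMENT_ORDER[self.mention.element],
        )


def match_elements(
    text: str,
    lexicon: PrefixLexicon,
    rules: Optional[Sequence[MatchRule]] = None,
    params: Optional[HmmParams] = None,
    depth_cap: int = DEFAULT_DEPTH_CAP,
) -> ExtractionResult:
    """Extract the diagnostic elements of one diagnosis text.

    Pipeline: segment → multilevel re-segmentation → rule matching over
    tokens and sub-entities (literal and class rules) and over the raw text
    (regex rules); Knosp expressions go through :func:`parse_knosp` at top
    priority. Each span feeds at most one mention: candidates are accepted
    greedily by (priority desc, match length desc, position), skipping any
    that overlap an accepted mention.
    """
    text = nfc(text)
    if rules is None:
        rules = default_rules()
    if not text:
        return ExtractionResult(text, [])

    candidates: list[_Candidate] = []
    seen: set[tuple[str, int, int]] = set()

    def add(element: str, span: Span, priority: int) -> None:
        key = (element, span.start, span.end)
        if key in seen:
            return
        seen.add(key)
        candidates.append(
            _Candidate(priority, span, ElementMention(element, text[span.start : span.end], span))
        )

    for km in parse_knosp(text):
        add("knosp_grade", km.span, KNOSP_PRIORITY)

    tokens = segment(text, lexicon, params)
    nodes: list[NestedEntity] = []
    for token in tokens:
        if token.origin == "oov":
            continue
        if len(token.surface) == 1 and is_break_char(token.surface):
            continue
        nodes.extend(multilevel_segment(token, lexicon, depth_cap).walk())

    literal_rules = [r for r in rules if r.kind == "literal"]
    class_rules = [r for r in rules if r.kind == "class"]
    regex_rules = [r for r in rules if r.kind == "regex"]

    for node in nodes:
        if node.span is None:
            continue
        folded = node.word.casefold()
        for rule in literal_rules:
            if folded == rule.pattern:
                add(rule.element, node.span, rule.priority)
        for rule in class_rules:
            if node.entity_class == rule.pattern:
                add(rule.element, node.span, rule.priority)

    for rule in regex_rules:
        for match in rule._compiled.finditer(text):
            if match.start() < match.end():
                add(rule.element, Span(match.start(), match.end()), rule.priority)

    accepted: list[_Candidate] = []
    for cand in sorted(candidates, key=_Candidate.sort_key):
        if any(
            cand.span.start < other.span.end and other.span.start < cand.span.end
            for other in accepted
        ):
            continue
        accepted.append(cand)

    mentions = sorted((c.mention for c in accepted), key=lambda m: (m.span.start, m.span.end))
    return ExtractionResult(text, mentions)
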