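"""Word segmentation: DAG scan, max-probability path, BMES Viterbi fallback.

The pipeline mirrors dictionary-driven Chinese segmentation in "precise"
mode:

1.  a rule pre-pass marks maximal Latin-letter/digit runs (with the
    connectors ``/ - – .``) as *protected* atomic units, because character
    n-gram machinery handles numbers and case poorly;
2.  a word DAG is scanned over the prefix lexicon: an edge (i, j) exists
    whenever the text between the two positions is a dictionary word, plus
    the single-unit fallback edge;
3.  dynamic programming selects the segmentation maximizing the product of
    unigram word probabilities ``freq(w) / total_frequency`` (unknown single
    units receive a floor frequency of 1);
4.  maximal runs of unknown single characters are handed to a BMES
    (Begin/Middle/End/Single) character-tagging HMM decoded with Viterbi,
    which cuts plausible out-of-vocabulary words.

Path scores are compared in exact integer arithmetic — path ``p`` with word
frequencies ``f_1..f_k`` scores ``(∏ f_i) / T^k``, and two scores are
compared by cross-multiplying with the appropriate powers of ``T`` — so the
documented tie-break (prefer the longer word at the first point of
divergence) triggers on exact ties only and the output is platform-stable.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from ._text import is_break_char, nfc
from .lexicon import PrefixLexicon

#: Frequency assigned to single units absent from the lexicon.
FLOOR_FREQUENCY = 1

#: Maximal Latin/digit runs; '/', '-', en dash and '.' join runs only when
#: flanked by letters or digits on both sides ("GH/TSH", "2–3", "Knosp").
PROTECTED_RE = re.compile(r"[A-Za-z0-9]+(?:[/\-–.][A-Za-z0-9]+)*")

STATES = ("B", "M", "E", "S")
ALLOWED_TRANSITIONS = {
    "B": ("M", "E"),
    "M": ("M", "E"),
    "E": ("B", "S"),
    "S": ("B", "S"),
}
NEG_INF = float("-inf")


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [start, end) on NFC-normalized text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Token:
    """A segmented span. ``origin`` records which stage produced it:
    ``dictionary`` (DAG/DP), ``rule`` (protected run or punctuation), or
    ``oov`` (Viterbi fallback, always with entity class ``unknown``)."""

    surface: str
    span: Span
    entity_class: str = "unknown"
    origin: str = "dictionary"


@dataclass
class WordDAG:
    """All word-formation cases of a sentence: ``edges[i]`` lists every j such
    that text[i:j] is a dictionary word, plus the single-character fallback."""

    text: str
    edges: dict[int, list[int]]


def pre_tokenize_protected(text: str) -> list[tuple[Span, str]]:
    """Partition *text* into spans tagged ``protected`` (Latin/digit runs) and
    ``free`` (everything else). Expects NFC input; empty text gives []."""
    spans: list[tuple[Span, str]] = []
    pos = 0
    for match in PROTECTED_RE.finditer(text):
        if match.start() > pos:
            spans.append((Span(pos, match.start()), "free"))
        spans.append((Span(match.start(), match.end()), "protected"))
        pos = match.end()
    if pos < len(text):
        spans.append((Span(pos, len(text)), "free"))
    return spans


# ---------------------------------------------------------------------------
# Generic DAG + DP over "units" (characters, or protected runs treated as one
# unit). The public char-level API wraps the unit-level core.
# ---------------------------------------------------------------------------


def _units_for(text: str) -> list[tuple[Span, str]]:
    """Unit decomposition used by :func:`segment`: protected runs are one unit
    each; other characters are single units, classed ``char`` or ``break``."""
    units: list[tuple[Span, str]] = []
    for span, tag in pre_tokenize_protected(text):
        if tag == "protected":
            units.append((span, "protected"))
        else:
            for i in range(span.start, span.end):
                ch = text[i]
                units.append((Span(i, i + 1), "break" if is_break_char(ch) else "char"))
    return units


def _scan_words(
    text: str, units: Sequence[tuple[Span, str]], lexicon: PrefixLexicon
) -> tuple[dict[int, list[int]], dict[tuple[int, int], int]]:
    """Unit-level DAG edges and the frequencies of true dictionary words.

    The scan grows a candidate word unit by unit and stops as soon as the
    candidate is absent from the prefix table (prefix closure guarantees no
    longer word can start there). Break units never join words.
    """
    n = len(units)
    edges: dict[int, list[int]] = {}
    word_freq: dict[tuple[int, int], int] = {}
    table = lexicon.prefix_table
    for i in range(n):
        outs = {i + 1}
        if units[i][1] != "break":
            for j in range(i, n):
                if units[j][1] == "break":
                    break
                candidate = text[units[i][0].start : units[j][0].end]
                value = table.get(candidate)
                if value is None:
                    break
                if value > 0:
                    outs.add(j + 1)
                    word_freq[(i, j + 1)] = value
        edges[i] = sorted(outs)
    return edges, word_freq


def _max_prob_path(
    n: int,
    edges: dict[int, list[int]],
    word_freq: dict[tuple[int, int], int],
    total: int,
) -> list[tuple[int, int]]:
    """Best path through the unit DAG; returns the chosen (i, j) unit words.

    ``route[i]`` holds (product of frequencies, word count, next index) of the
    best suffix path. Candidates a=(pa, ka), b=(pb, kb) compare by
    ``pa * T**kb  <=>  pb * T**ka``; exact ties go to the larger j, which
    realizes "longer word first at the first point of divergence".
    """
    T = max(total, 1)
    route: list[tuple[int, int, int]] = [(0, 0, -1)] * (n + 1)
    route[n] = (1, 0, -1)
    for i in range(n - 1, -1, -1):
        best: tuple[int, int, int] | None = None
        for j in edges[i]:
            freq = word_freq.get((i, j), FLOOR_FREQUENCY)
            prod = freq * route[j][0]
            count = route[j][1] + 1
            if best is None:
                best = (prod, count, j)
                continue
            lhs = prod * T ** best[1]
            rhs = best[0] * T**count
            if lhs > rhs or (lhs == rhs and j > best[2]):
                best = (prod, count, j)
        assert best is not None  # the fallback edge always exists
        route[i] = best
    path: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = route[i][2]
        path.append((i, j))
        i = j
    return path


def build_word_dag(text: str, lexicon: PrefixLexicon) -> WordDAG:
    """Character-level word DAG of *text* (empty text gives an empty mapping)."""
    text = nfc(text)
    units = [(Span(i, i + 1), "char") for i in range(len(text))]
    edges, _ = _scan_words(text, units, lexicon)
    return WordDAG(text=text, edges=edges)


def max_prob_segment(text: str, dag: WordDAG, lexicon: PrefixLexicon) -> list[Token]:
    """Maximum-probability segmentation over a character-level DAG.

    Dictionary words carry their entity class; unknown single characters come
    out with origin ``oov`` (no Viterbi joining at this level — see
    :func:`segment` for the orchestrated pipeline).
    """
    text = nfc(text)
    n = len(text)
    if n == 0:
        return []
    units = [(Span(i, i + 1), "char") for i in range(n)]
    _, word_freq = _scan_words(text, units, lexicon)
    edges = {i: sorted(set(dag.edges.get(i, [i + 1])) | {i + 1}) for i in range(n)}
    path = _max_prob_path(n, edges, word_freq, lexicon.total_frequency)
    tokens: list[Token] = []
    for i, j in path:
        surface = text[i:j]
        entry = lexicon.lookup(surface) if (i, j) in word_freq else None
        if entry is not None:
            tokens.append(Token(surface, Span(i, j), entry.entity_class, "dictionary"))
        else:
            tokens.append(Token(surface, Span(i, j), "unknown", "oov"))
    return tokens


# ---------------------------------------------------------------------------
# BMES hidden Markov model for out-of-vocabulary fragments
# ---------------------------------------------------------------------------


@dataclass
class HmmParams:
    """Log-probability tables of the BMES character-tagging HMM.

    Transitions outside the BMES word grammar (B→{M,E}, M→{M,E}, E→{B,S},
    S→{B,S}) are −∞, as are the initial probabilities of M and E; characters
    unseen in training emit at the per-state ``emit_floor``.
    """

    start: dict[str, float]
    trans: dict[str, dict[str, float]]
    emit: dict[str, dict[str, float]]
    emit_floor: dict[str, float]

    def emission(self, state: str, ch: str) -> float:
        return self.emit[state].get(ch, self.emit_floor[state])

    def to_json(self) -> str:
        return json.dumps(
            {
                "start": self.start,
                "trans": self.trans,
                "emit": self.emit,
                "emit_floor": self.emit_floor,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "HmmParams":
        payload = json.loads(text)
        return cls(
            start=payload["start"],
            trans={s: dict(row) for s, row in payload["trans"].items()},
            emit={s: dict(row) for s, row in payload["emit"].items()},
            emit_floor=payload["emit_floor"],
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "HmmParams":
        return cls.from_json(Path(path).read_text("utf-8"))

    @classmethod
    def from_segmented(cls, lines: Iterable[str]) -> "HmmParams":
        """Maximum-likelihood estimates with add-one smoothing from a
        pre-segmented corpus (words separated by whitespace, one sentence per
        line). This is how the packaged default parameters are produced."""
        start_counts = {"B": 0, "S": 0}
        trans_counts = {s: {t: 0 for t in ALLOWED_TRANSITIONS[s]} for s in STATES}
        emit_counts: dict[str, dict[str, int]] = {s: {} for s in STATES}
        vocab: set[str] = set()
        for raw in lines:
            words = nfc(raw).split()
            if not words:
                continue
            tags: list[str] = []
            chars: list[str] = []
            for word in words:
                if len(word) == 1:
                    tags.append("S")
                else:
                    tags.extend(["B"] + ["M"] * (len(word) - 2) + ["E"])
                chars.extend(word)
            start_counts[tags[0]] += 1
            for tag, ch in zip(tags, chars):
                emit_counts[tag][ch] = emit_counts[tag].get(ch, 0) + 1
                vocab.add(ch)
            for a, b in zip(tags, tags[1:]):
                if b in trans_counts[a]:
                    trans_counts[a][b] += 1
        v = len(vocab)
        start_total = sum(start_counts.values()) + 2
        start = {s: NEG_INF for s in STATES}
        for s in ("B", "S"):
            start[s] = math.log((start_counts[s] + 1) / start_total)
        trans = {s: {t: NEG_INF for t in STATES} for s in STATES}
        for s in STATES:
            total = sum(trans_counts[s].values()) + len(ALLOWED_TRANSITIONS[s])
            for t in ALLOWED_TRANSITIONS[s]:
                trans[s][t] = math.log((trans_counts[s][t] + 1) / total)
        emit: dict[str, dict[str, float]] = {}
        emit_floor: dict[str, float] = {}
        for s in STATES:
            total = sum(emit_counts[s].values()) + v + 1
            emit[s] = {ch: math.log((c + 1) / total) for ch, c in emit_counts[s].items()}
            emit_floor[s] = math.log(1 / total)
        return cls(start=start, trans=trans, emit=emit, emit_floor=emit_floor)


_DEFAULT_HMM: Optional[HmmParams] = None


def default_hmm_params() -> HmmParams:
    """Parameters estimated from the packaged segmented mini-corpus (cached)."""
    global _DEFAULT_HMM
    if _DEFAULT_HMM is None:
        text = resources.files("padx.data").joinpath("hmm_corpus.txt").read_text("utf-8")
        _DEFAULT_HMM = HmmParams.from_segmented(text.splitlines())
    return _DEFAULT_HMM


def viterbi_tags(fragment: str, params: HmmParams) -> str:
    """Most probable BMES tag sequence for *fragment* (first tag in {B,S},
    last in {E,S}). Ties break toward the earlier state in B,M,E,S order."""
    if not fragment:
        return ""
    n = len(fragment)
    if n == 1:
        return "S"
    score = {s: params.start[s] + params.emission(s, fragment[0]) for s in STATES}
    back: list[dict[str, str]] = []
    for idx in range(1, n):
        ch = fragment[idx]
        new_score: dict[str, float] = {}
        pointers: dict[str, str] = {}
        for s in STATES:
            best_prev, best_val = None, NEG_INF
            for p in STATES:
                val = score[p] + params.trans[p][s]
                if val > best_val:
                    best_prev, best_val = p, val
            new_score[s] = best_val + params.emission(s, ch)
            pointers[s] = best_prev if best_prev is not None else "S"
        score = new_score
        back.append(pointers)
    last = max(("E", "S"), key=lambda s: score[s])
    tags = [last]
    for pointers in reversed(back):
        tags.append(pointers[tags[-1]])
    return "".join(reversed(tags))


def viterbi_oov(fragment: str, params: HmmParams) -> list[Token]:
    """Cut an out-of-vocabulary fragment into words via the BMES tag path.

    Tokens are cut at S tags and at B..E groups; they concatenate exactly to
    the fragment, carry origin ``oov`` and entity class ``unknown``. Spans
    are relative to the fragment.
    """
    if not fragment:
        return []
    tags = viterbi_tags(fragment, params)
    tokens: list[Token] = []
    start = 0
    for idx, tag in enumerate(tags):
        if tag in ("E", "S"):
            tokens.append(
                Token(fragment[start : idx + 1], Span(start, idx + 1), "unknown", "oov")
            )
            start = idx + 1
    if start < len(fragment):  # trailing B/M run (tag path cannot end mid-word,
        tokens.append(  # but guard keeps the concatenation invariant)
            Token(fragment[start:], Span(start, len(fragment)), "unknown", "oov")
        )
    return tokens


# ---------------------------------------------------------------------------
# Orchestrated pipeline
# ---------------------------------------------------------------------------


def segment(
    text: str, lexicon: PrefixLexicon, params: Optional[HmmParams] = None
) -> list[Token]:
    """Full segmentation of *text*: rule pre-pass, DAG + DP, Viterbi fallback.

    Protected runs are atomic units that pass through as ``rule`` tokens
    unless a dictionary word spans them (compound medical terms embedding
    Latin abbreviations remain single dictionary tokens). Punctuation and
    whitespace come out as single ``rule`` tokens and never join words.
    Tokens cover the NFC text exactly, in order.
    """
    text = nfc(text)
    if not text:
        return []
    if params is None:
        params = default_hmm_params()
    units = _units_for(text)
    n = len(units)
    edges, word_freq = _scan_words(text, units, lexicon)
    path = _max_prob_path(n, edges, word_freq, lexicon.total_frequency)

    tokens: list[Token] = []
    pending: list[int] = []  # run of unknown single 'char' units for the HMM

    def flush_pending() -> None:
        if not pending:
            return
        start = units[pending[0]][0].start
        end = units[pending[-1]][0].end
        fragment = text[start:end]
        for tok in viterbi_oov(fragment, params):
            tokens.append(
                Token(
                    tok.surface,
                    Span(start + tok.span.start, start + tok.span.end),
                    "unknown",
                    "oov",
                )
            )
        pending.clear()

    for i, j in path:
        span = Span(units[i][0].start, units[j - 1][0].end)
        surface = text[span.start : span.end]
        if (i, j) in word_freq:
            flush_pending()
            entry = lexicon.lookup(surface)
            assert entry is not None
            tokens.append(Token(surface, span, entry.entity_class, "dictionary"))
        else:
            kind = units[i][1]
            if kind == "char":
                pending.append(i)
            else:  # protected run or break character
                flush_pending()
                tokens.append(Token(surface, span, "other", "rule"))
    flush_pending()
    return tokens
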