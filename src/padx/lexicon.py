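"""Medical dictionary supporting word-graph scanning.

The segmenter needs, for every start position in a sentence, all dictionary
words beginning there. A prefix lexicon makes that scan linear: every proper
prefix of every word is present in ``prefix_table`` (with value 0 when the
prefix is not itself a word), so the scan can stop as soon as a prefix is
unknown.

Dictionary files are UTF-8, one term per line, whitespace separated::

    垂体 8000 organ
    ACTH 1500 medicine
    复发 2000           # entity class defaults to "other"

Entity classes are an open vocabulary; the packaged lexicon uses
``organ, disease, medicine, endocrine, modifier, examination, drug, other``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from ._text import nfc

logger = logging.getLogger(__name__)

DEFAULT_ENTITY_CLASS = "other"

#: Seed vocabulary of entity classes; user dictionaries may introduce others.
KNOWN_ENTITY_CLASSES = frozenset(
    {
        "disease",
        "organ",
        "medicine",
        "other",
        "endocrine",
        "modifier",
        "examination",
        "drug",
    }
)


class LexiconParseError(ValueError):
    """A dictionary line that cannot be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary word: surface form, frequency count and entity class."""

    surface: str
    frequency: int
    entity_class: str = DEFAULT_ENTITY_CLASS

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("lexicon surface must be non-empty")
        if any(ch.isspace() for ch in self.surface):
            raise ValueError(f"lexicon surface contains whitespace: {self.surface!r}")
        if self.frequency < 0:
            raise ValueError(f"negative frequency for {self.surface!r}")


Source = Union[str, Path, IO[str], Iterable[str]]


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def parse_lexicon_file(source: Source) -> list[LexiconEntry]:
    """Parse a dictionary stream (path, open file, or iterable of lines).

    Blank lines are skipped. Each remaining line must hold 2-3 fields:
    surface, frequency (positive integer) and an optional entity class.
    Malformed lines raise :class:`LexiconParseError` naming the line.
    """
    entries: list[LexiconEntry] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise LexiconParseError(lineno, f"expected 2-3 fields, got {len(fields)}")
        surface = nfc(fields[0])
        try:
            frequency = int(fields[1])
        except ValueError:
            raise LexiconParseError(lineno, f"frequency is not an integer: {fields[1]!r}") from None
        if frequency < 1:
            raise LexiconParseError(lineno, f"frequency must be >= 1, got {frequency}")
        entity_class = fields[2] if len(fields) == 3 else DEFAULT_ENTITY_CLASS
        entries.append(LexiconEntry(surface, frequency, entity_class))
    return entries


def serialize_lexicon(entries: Iterable[LexiconEntry]) -> str:
    """Inverse of :func:`parse_lexicon_file` (always writes the entity class)."""
    return "".join(f"{e.surface} {e.frequency} {e.entity_class}\n" for e in entries)


@dataclass
class PrefixLexicon:
    """Dictionary closed under prefixes, the structure driving the DAG scan.

    ``prefix_table`` maps every word *and every proper prefix of a word* to an
    integer: true words carry their frequency, pure prefixes carry 0. The
    invariant "value > 0 implies real entry" is what lets the segmenter treat
    the table as both membership test and frequency source.
    """

    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    prefix_table: dict[str, int] = field(default_factory=dict)
    total_frequency: int = 0

    @property
    def usable(self) -> bool:
        """False for an empty lexicon, whose frequencies cannot score paths."""
        return self.total_frequency > 0

    def add(self, entry: LexiconEntry) -> None:
        surface = nfc(entry.surface)
        existing = self.entries.get(surface)
        if existing is not None:
            # Collisions: frequencies accumulate, the first entity class wins.
            merged = LexiconEntry(
                surface, existing.frequency + entry.frequency, existing.entity_class
            )
            if entry.entity_class != existing.entity_class:
                logger.warning(
                    "duplicate lexicon surface %r: keeping class %r, ignoring %r",
                    surface,
                    existing.entity_class,
                    entry.entity_class,
                )
            self.entries[surface] = merged
            self.prefix_table[surface] = merged.frequency
            self.total_frequency += entry.frequency
            return
        self.entries[surface] = LexiconEntry(surface, entry.frequency, entry.entity_class)
        for i in range(1, len(surface)):
            self.prefix_table.setdefault(surface[:i], 0)
        self.prefix_table[surface] = entry.frequency
        self.total_frequency += entry.frequency

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        """The entry for *surface* iff it is a true word; pure prefixes yield None."""
        surface = nfc(surface)
        if self.prefix_table.get(surface, 0) > 0:
            return self.entries[surface]
        return None

    def __contains__(self, surface: str) -> bool:
        return self.lookup(surface) is not None

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_entries(cls, entries: Iterable[LexiconEntry]) -> "PrefixLexicon":
        lex = cls()
        for entry in entries:
            lex.add(entry)
        return lex

    @classmethod
    def from_files(cls, *paths: Union[str, Path]) -> "PrefixLexicon":
        """Merge several dictionary files in order (base dictionary, then additions)."""
        lex = cls()
        for path in paths:
            for entry in parse_lexicon_file(path):
                lex.add(entry)
        return lex


def build_prefix_lexicon(entries: Iterable[LexiconEntry]) -> PrefixLexicon:
    """Build a :class:`PrefixLexicon`; duplicate surfaces are merged (see ``add``)."""
    return PrefixLexicon.from_entries(entries)


def lookup(lexicon: PrefixLexicon, surface: str) -> Optional[LexiconEntry]:
    """Module-level convenience wrapper around :meth:`PrefixLexicon.lookup`."""
    return lexicon.lookup(surface)


def load_default_lexicon() -> PrefixLexicon:
    """The packaged pituitary-adenoma mini-lexicon (locations, hormones, size
    morphemes, Knosp vocabulary, histopathology words, modifiers)."""
    text = resources.files("padx.data").joinpath("pa_lexicon.txt").read_text("utf-8")
    return PrefixLexicon.from_entries(parse_lexicon_file(text.splitlines()))
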