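"""Lexicon construction and dictionary-based entity recognition with linking.

The food lexicon is built from pipe-delimited concept tables in the UMLS
Rich Release Format dialect: a semantic-type table (MRSTY-like) selects
the concept identifiers carrying a given semantic type (default "Food"),
and a concept-names table (MRCONSO-like) supplies every English surface
form of those concepts. Matching is case-insensitive, token-boundary
respecting, and resolves overlaps with the standard gazetteer
leftmost-longest rule. Because every lexicon surface carries its concept
identifier, recognition performs entity linking for free.

Disease and chemical recognizers are pluggable through the
:class:`EntityRecognizer` contract; the bundled fallback is the same
dictionary engine loaded with a different lexicon and entity class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol, runtime_checkable

from relmine.corpus_io import Sentence
from relmine.errors import ConfigurationError, ContractViolationError

logger = logging.getLogger(__name__)

ENTITY_CLASSES = frozenset({"FOOD", "CHEMICAL", "DISEASE"})


def normalize_surface(surface: str) -> str:
    """Case-fold and collapse internal whitespace; the only normalization."""
    return " ".join(surface.split()).casefold()


@dataclass(frozen=True)
class LexiconEntry:
    """One (concept identifier, matchable name) pair.

    ``surface`` is stored normalized; ``source_kb`` labels the knowledge
    base the identifier lives in (e.g. "UMLS").
    """

    concept_id: str
    surface: str
    source_kb: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("lexicon surface empty after normalization")


@dataclass
class Lexicon:
    """A deduplicated set of lexicon entries built under one type filter."""

    entries: list[LexiconEntry] = field(default_factory=list)
    semantic_type_label: str = ""

    @property
    def entry_count(self) -> int:
        return len(self.entries)

    @property
    def concept_ids(self) -> set[str]:
        return {e.concept_id for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)


@dataclass(frozen=True)
class EntityMention:
    """A typed, offset-anchored surface string linked to an identifier.

    Offsets are 0-based half-open into the *sentence* text. Linking is
    mandatory: candidates without a concept identifier are never emitted.
    """

    doc_id: str
    sentence_index: int
    char_start: int
    char_end: int
    surface: str
    entity_class: str
    concept_id: str
    source_kb: str = ""

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {self.entity_class!r}")
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty (linking is mandatory)")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end


def _read_rrf_rows(path: str | Path) -> Iterator[list[str]]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            if fields and fields[-1] == "":
                fields = fields[:-1]  # trailing pipe tolerated
            yield fields


def build_food_lexicon(
    mrsty_path: str | Path,
    mrconso_path: str | Path,
    semantic_type_label: str = "Food",
    *,
    mrsty_cui_col: int = 0,
    mrsty_type_col: int = 3,
    mrconso_cui_col: int = 0,
    mrconso_lang_col: int = 1,
    mrconso_str_col: int = 14,
    language: str = "ENG",
    source_kb: str = "UMLS",
) -> Lexicon:
    """Two-step lexicon construction from RRF-dialect tables.

    Step 1 collects the identifiers of every concept whose semantic type
    equals ``semantic_type_label`` from the MRSTY-like table; step 2
    collects every English name of those concepts from the MRCONSO-like
    table. Surfaces are deduplicated after case-folding and whitespace
    normalization. Column positions are configurable and default to the
    UMLS layout (MRSTY: CUI at 0, type name at 3; MRCONSO: CUI at 0,
    language at 1, string at 14).
    """
    wanted: set[str] = set()
    for row in _read_rrf_rows(mrsty_path):
        if len(row) > mrsty_type_col and row[mrsty_type_col] == semantic_type_label:
            wanted.add(row[mrsty_cui_col])
    if not wanted:
        logger.warning(
            "no concepts with semantic type %r in %s; lexicon is empty",
            semantic_type_label,
            mrsty_path,
        )
        return Lexicon([], semantic_type_label=semantic_type_label)
    seen: set[tuple[str, str]] = set()
    for row in _read_rrf_rows(mrconso_path):
        if len(row) <= mrconso_str_col:
            continue
        cui = row[mrconso_cui_col]
        if cui not in wanted or row[mrconso_lang_col] != language:
            continue
        surface = normalize_surface(row[mrconso_str_col])
        if surface:
            seen.add((cui, surface))
    entries = [
        LexiconEntry(concept_id=cui, surface=surface, source_kb=source_kb)
        for cui, surface in sorted(seen)
    ]
    return Lexicon(entries, semantic_type_label=semantic_type_label)


def load_lexicon_tsv(
    path: str | Path, semantic_type_label: str = "", source_kb: str = ""
) -> Lexicon:
    """Load a lexicon from a two-column TSV: ``concept_id<TAB>surface``."""
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            surface = normalize_surface(parts[1])
            if surface:
                seen.add((parts[0], surface))
    entries = [
        LexiconEntry(concept_id=cid, surface=surface, source_kb=source_kb)
        for cid, surface in sorted(seen)
    ]
    return Lexicon(entries, semantic_type_label=semantic_type_label)


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for entry in sorted(lexicon, key=lambda e: (e.concept_id, e.surface)):
            fh.write(f"{entry.concept_id}\t{entry.surface}\n")
    return path


_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def _tokenize(text: str) -> list[tuple[int, int, str]]:
    """Alphanumeric-run tokens with offsets; the token-boundary definition."""
    return [(m.start(), m.end(), m.group().casefold()) for m in _TOKEN_RE.finditer(text)]


class _SurfaceIndex:
    """Token-indexed multi-pattern scanner for a lexicon.

    Surfaces are indexed by their first token; a candidate match must
    align token-for-token and its normalized raw span must equal the
    lexicon surface (so "fish  oil" matches "fish oil" but "fish-oil"
    does not).
    """

    def __init__(self, lexicon: Lexicon):
        self.by_first: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        chosen: dict[str, str] = {}  # surface -> smallest concept_id (deterministic)
        for entry in lexicon:
            prev = chosen.get(entry.surface)
            if prev is None or entry.concept_id < prev:
                chosen[entry.surface] = entry.concept_id
        for surface, concept_id in chosen.items():
            tokens = tuple(t for _, _, t in _tokenize(surface))
            if not tokens:
                continue
            self.by_first.setdefault(tokens[0], []).append((tokens, surface, concept_id))
        for candidates in self.by_first.values():
            candidates.sort(key=lambda c: -len(c[0]))  # longest token span first

    def scan(self, text: str) -> list[tuple[int, int, str, str]]:
        """All raw matches as (char_start, char_end, surface, concept_id)."""
        tokens = _tokenize(text)
        matches = []
        for i, (start, _, tok) in enumerate(tokens):
            for pattern, surface, concept_id in self.by_first.get(tok, ()):
                j = i + len(pattern)
                if j > len(tokens):
                    continue
                if tuple(t for _, _, t in tokens[i:j]) != pattern:
                    continue
                end = tokens[j - 1][1]
                if normalize_surface(text[start:end]) == surface:
                    matches.append((start, end, text[start:end], concept_id))
        return matches


def resolve_leftmost_longest(
    matches: Iterable[tuple[int, int, str, str]],
) -> list[tuple[int, int, str, str]]:
    """Standard gazetteer overlap resolution: leftmost match wins; among
    matches starting at the same position the longest wins; accepted
    matches exclude anything overlapping them."""
    ordered = sorted(matches, key=lambda m: (m[0], -(m[1] - m[0])))
    accepted: list[tuple[int, int, str, str]] = []
    last_end = 0
    for m in ordered:
        if m[0] >= last_end:
            accepted.append(m)
            last_end = m[1]
    return accepted


@runtime_checkable
class EntityRecognizer(Protocol):
    """Contract for pluggable disease/chemical (or food) recognizers.

    Implementations declare the entity class they emit and the knowledge
    base their identifiers link to, and must return mentions satisfying
    the :class:`EntityMention` invariants.
    """

    entity_class: str
    source_kb: str

    def recognize(self, sentence: Sentence) -> list[EntityMention]: ...


class DictionaryRecognizer:
    """Dictionary NER + NEL over a lexicon; the bundled fallback engine.

    The same engine serves all three entity classes: food recognition by
    design, disease/chemical recognition as an offline fallback for
    model-based recognizers honoring the same contract.
    """

    def __init__(self, lexicon: Lexicon, entity_class: str, source_kb: str = ""):
        if entity_class not in ENTITY_CLASSES:
            raise ConfigurationError(f"unknown entity class {entity_class!r}")
        self.lexicon = lexicon
        self.entity_class = entity_class
        self.source_kb = source_kb
        self._index = _SurfaceIndex(lexicon)

    def recognize(self, sentence: Sentence) -> list[EntityMention]:
        resolved = resolve_leftmost_longest(self._index.scan(sentence.text))
        return [
            EntityMention(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                char_start=start,
                char_end=end,
                surface=surface,
                entity_class=self.entity_class,
                concept_id=concept_id,
                source_kb=self.source_kb,
            )
            for start, end, surface, concept_id in resolved
        ]


def match_food_entities(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    """Dictionary food NER with UMLS-style linking on one sentence."""
    return DictionaryRecognizer(lexicon, "FOOD", source_kb="UMLS").recognize(sentence)


def recognize_entities(
    sentence: Sentence, recognizer: EntityRecognizer
) -> list[EntityMention]:
    """Run a pluggable recognizer, enforcing its declared contract."""
    mentions = recognizer.recognize(sentence)
    for mention in mentions:
        if mention.entity_class != recognizer.entity_class:
            raise ContractViolationError(
                f"recognizer declared {recognizer.entity_class} but emitted a "
                f"{mention.entity_class} mention {mention.surface!r}"
            )
        if sentence.text[mention.char_start : mention.char_end] != mention.surface:
            raise ContractViolationError(
                f"mention offsets do not reproduce surface {mention.surface!r} in "
                f"sentence ({sentence.doc_id}, {sentence.index})"
            )
    return mentions
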