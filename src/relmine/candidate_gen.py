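"""Sentence-role filtering, candidate pair enumeration, and entity masking.

Abstracts mix research findings with statements of objective, hypothesis
and methodology; only sentences expressing facts or analysis are a
reliable source of relations, so candidate pairs are generated only from
FACT/ANALYSIS sentences. Eligible typed entity pairs are the full
cross-product of the schema's two classes within one sentence, and each
pair's sentence text is masked (entity spans replaced by class-specific
placeholders) so relation classifiers judge the context words rather
than the specific entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

from relmine.corpus_io import Sentence
from relmine.errors import ConfigurationError, InvariantViolationError
from relmine.lexicon_ner import ENTITY_CLASSES, EntityMention

ROLE_LABELS = frozenset({"FACT", "ANALYSIS", "OBJECTIVE", "HYPOTHESIS", "METHOD", "OTHER"})
#: Roles admitted to relation extraction.
EVIDENCE_ROLES = frozenset({"FACT", "ANALYSIS"})

RELATION_LABELS = frozenset({"CAUSE", "TREAT", "CONTAINS"})

#: Placeholder tokens used when masking entity spans; chosen to be
#: visually distinct and impossible to confuse with lexicon surfaces.
PLACEHOLDERS = {"FOOD": "@FOOD$", "CHEMICAL": "@CHEMICAL$", "DISEASE": "@DISEASE$"}


@dataclass(frozen=True)
class PairSchema:
    """A typed pair template and the relations allowed for it."""

    name: str
    class_a: str
    class_b: str
    relations: frozenset

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ConfigurationError("schema classes must differ")
        if self.class_a not in ENTITY_CLASSES or self.class_b not in ENTITY_CLASSES:
            raise ConfigurationError("schema classes must be FOOD/CHEMICAL/DISEASE")
        if not self.relations <= RELATION_LABELS:
            raise ConfigurationError(f"unknown relations: {set(self.relations) - RELATION_LABELS}")


FOODIS_SCHEMA = PairSchema("foodis", "FOOD", "DISEASE", frozenset({"CAUSE", "TREAT"}))
CHEMDIS_SCHEMA = PairSchema("chemdis", "CHEMICAL", "DISEASE", frozenset({"CAUSE", "TREAT"}))
FOODCHEM_SCHEMA = PairSchema("foodchem", "FOOD", "CHEMICAL", frozenset({"CONTAINS"}))

SCHEMAS = {s.name: s for s in (FOODIS_SCHEMA, CHEMDIS_SCHEMA, FOODCHEM_SCHEMA)}


@dataclass(frozen=True)
class CandidatePair:
    """One typed entity pair in one sentence, with its masked text.

    Orientation is fixed by the schema as (class_a, class_b) regardless
    of the textual order of the mentions.
    """

    sentence: Sentence
    mention_a: EntityMention
    mention_b: EntityMention
    masked_text: str


@runtime_checkable
class RoleClassifier(Protocol):
    """Contract for pluggable rhetorical-role classifiers."""

    def classify(self, sentence: Sentence) -> str: ...


#: Default cue phrases, checked casefolded as substrings, in this order.
DEFAULT_CUES: dict[str, tuple[str, ...]] = {
    "OBJECTIVE": (
        "we aimed",
        "we aim to",
        "the aim of this study",
        "the objective of this study",
        "the purpose of this study",
        "this study aims",
        "this study aimed",
        "the goal of this study",
    ),
    "HYPOTHESIS": (
        "we hypothesize",
        "we hypothesized",
        "it is hypothesized",
        "it was hypothesized",
        "we postulate",
        "we postulated",
        "our hypothesis",
    ),
    "METHOD": (
        "was performed",
        "were performed",
        "was conducted",
        "were conducted",
        "were randomly assigned",
        "were recruited",
        "we enrolled",
        "samples were collected",
        "data were collected",
    ),
}


class CueRoleClassifier:
    """Heuristic role classifier over a configurable cue-phrase table.

    A sentence containing a cue for OBJECTIVE, HYPOTHESIS or METHOD (in
    that priority order) receives that label; an empty sentence is OTHER;
    everything else is treated as FACT. This mirrors the conservative
    reading that unflagged abstract sentences state findings or known
    facts.
    """

    def __init__(self, cues: dict[str, Sequence[str]] | None = None):
        cues = dict(DEFAULT_CUES) if cues is None else cues
        unknown = set(cues) - ROLE_LABELS
        if unknown:
            raise ConfigurationError(f"cue table has unknown roles: {sorted(unknown)}")
        self.cues = {role: tuple(p.casefold() for p in phrases) for role, phrases in cues.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "CueRoleClassifier":
        """Load cues from a plain-text file: ``ROLE<TAB>phrase`` per line,
        ``#`` starts a comment."""
        cues: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ConfigurationError(f"{path}:{lineno}: expected ROLE<TAB>phrase")
                cues.setdefault(parts[0].strip().upper(), []).append(parts[1].strip())
        return cls(cues)

    def classify(self, sentence: Sentence) -> str:
        text = sentence.text.casefold()
        if not text.strip():
            return "OTHER"
        for role in ("OBJECTIVE", "HYPOTHESIS", "METHOD"):
            if any(p in text for p in self.cues.get(role, ())):
                return role
        return "FACT"


def classify_sentence_role(
    sentence: Sentence, classifier: RoleClassifier | None = None
) -> str:
    """Assign a rhetorical role; defaults to the bundled cue heuristic."""
    classifier = classifier or CueRoleClassifier()
    label = classifier.classify(sentence)
    if label not in ROLE_LABELS:
        raise ConfigurationError(f"role classifier returned unknown label {label!r}")
    return label


def mask_pair(
    sentence: Sentence, mention_a: EntityMention, mention_b: EntityMention
) -> str:
    """Replace the two mention spans by class placeholders.

    Replacement proceeds right-to-left so the earlier span's offsets stay
    valid; all other text is unchanged. Overlapping spans violate the
    CandidatePair invariant and raise.
    """
    if mention_a.overlaps(mention_b):
        raise InvariantViolationError(
            f"mention spans overlap in sentence ({sentence.doc_id}, {sentence.index})"
        )
    text = sentence.text
    for m in sorted((mention_a, mention_b), key=lambda m: -m.char_start):
        if not (0 <= m.char_start <= m.char_end <= len(text)):
            raise InvariantViolationError("mention span outside sentence")
        text = text[: m.char_start] + PLACEHOLDERS[m.entity_class] + text[m.char_end :]
    return text


def enumerate_candidate_pairs(
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    schema: PairSchema,
    role: str = "FACT",
) -> list[CandidatePair]:
    """Enumerate eligible (class_a, class_b) pairs in one sentence.

    Sentences whose role is not FACT or ANALYSIS yield no pairs. The
    result is the full cross-product of class_a x class_b mentions,
    excluding pairs whose spans overlap; each pair carries its masked
    text.
    """
    if role not in EVIDENCE_ROLES:
        return []
    mentions_a = [m for m in mentions if m.entity_class == schema.class_a]
    mentions_b = [m for m in mentions if m.entity_class == schema.class_b]
    pairs = []
    for a in mentions_a:
        for b in mentions_b:
            if a.overlaps(b):
                continue
            pairs.append(
                CandidatePair(
                    sentence=sentence,
                    mention_a=a,
                    mention_b=b,
                    masked_text=mask_pair(sentence, a, b),
                )
            )
    return pairs
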