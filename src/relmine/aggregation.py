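"""Merging per-sentence relations into 6-tuple relation records.

A relation is determined by all sentences where information about it is
presented — its *supporting sentences*, which may come from the same or
different abstracts. Sentence-level relations are merged on the linked
concept identifiers, never on surface strings, so different synonyms of
the same concept fall into one record and the record's synonym sets are
well defined. The output record is the 6-tuple (name of entity A, name
of entity B, synonyms of A, synonyms of B, relation, supporting
sentences), plus the identifier merge keys.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from relmine.relation_ensemble import SentenceRelation


@dataclass(frozen=True)
class SupportingSentence:
    doc_id: str
    sentence_index: int
    text: str


@dataclass(frozen=True)
class RelationRecord:
    """An aggregated relation with its evidence.

    ``concept_id_a``/``concept_id_b`` are the merge keys; representative
    names are the most frequent observed surface per concept (ties broken
    lexicographically) and are always members of their synonym sets.
    Orientation is fixed: CAUSE/TREAT read A causes/treats B with B the
    disease; CONTAINS reads "A contains B" with A the food.
    """

    concept_id_a: str
    concept_id_b: str
    relation: str
    class_a: str
    class_b: str
    name_a: str
    name_b: str
    synonyms_a: tuple
    synonyms_b: tuple
    supporting_sentences: tuple
    source_kb_a: str = ""
    source_kb_b: str = ""

    def __post_init__(self) -> None:
        if not self.supporting_sentences:
            raise ValueError("supporting_sentences must be non-empty")
        addresses = [(s.doc_id, s.sentence_index) for s in self.supporting_sentences]
        if len(addresses) != len(set(addresses)):
            raise ValueError("duplicate supporting-sentence addresses in one record")
        if self.name_a not in self.synonyms_a or self.name_b not in self.synonyms_b:
            raise ValueError("representative names must be members of their synonym sets")

    @property
    def key(self) -> tuple:
        return (self.concept_id_a, self.concept_id_b, self.relation)

    @property
    def support(self) -> int:
        return len(self.supporting_sentences)


def _representative(counter: Counter) -> str:
    # most frequent surface; ties broken lexicographically
    top = max(counter.values())
    return min(s for s, c in counter.items() if c == top)


def aggregate_relations(
    sentence_relations: Iterable[SentenceRelation],
) -> list[RelationRecord]:
    """Merge sentence-level relations into records keyed by
    (concept_id_a, concept_id_b, relation).

    Supporting sentences are deduplicated by (doc_id, sentence_index)
    within a record and ordered by address; synonym sets are the union of
    observed surfaces per concept. The result is sorted by key, so
    aggregation is invariant to input order.
    """
    groups: dict[tuple, dict] = {}
    for sr in sentence_relations:
        a, b = sr.pair.mention_a, sr.pair.mention_b
        key = (a.concept_id, b.concept_id, sr.label)
        g = groups.setdefault(
            key,
            {
                "class_a": a.entity_class,
                "class_b": b.entity_class,
                "source_kb_a": a.source_kb,
                "source_kb_b": b.source_kb,
                "surfaces_a": Counter(),
                "surfaces_b": Counter(),
                "sentences": {},
            },
        )
        g["surfaces_a"][a.surface] += 1
        g["surfaces_b"][b.surface] += 1
        address = (sr.pair.sentence.doc_id, sr.pair.sentence.index)
        g["sentences"].setdefault(address, sr.pair.sentence.text)
    records = []
    for key in sorted(groups):
        g = groups[key]
        sentences = tuple(
            SupportingSentence(doc_id, idx, g["sentences"][(doc_id, idx)])
            for doc_id, idx in sorted(g["sentences"])
        )
        records.append(
            RelationRecord(
                concept_id_a=key[0],
                concept_id_b=key[1],
                relation=key[2],
                class_a=g["class_a"],
                class_b=g["class_b"],
                name_a=_representative(g["surfaces_a"]),
                name_b=_representative(g["surfaces_b"]),
                synonyms_a=tuple(sorted(g["surfaces_a"])),
                synonyms_b=tuple(sorted(g["surfaces_b"])),
                supporting_sentences=sentences,
                source_kb_a=g["source_kb_a"],
                source_kb_b=g["source_kb_b"],
            )
        )
    return records


def support_distribution(records: Iterable[RelationRecord]) -> dict[int, int]:
    """Histogram of number of records per supporting-sentence count."""
    hist = Counter(r.support for r in records)
    return dict(sorted(hist.items()))


def write_records_jsonl(records: Sequence[RelationRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            obj = {
                "concept_id_a": r.concept_id_a,
                "concept_id_b": r.concept_id_b,
                "relation": r.relation,
                "class_a": r.class_a,
                "class_b": r.class_b,
                "name_a": r.name_a,
                "name_b": r.name_b,
                "synonyms_a": list(r.synonyms_a),
                "synonyms_b": list(r.synonyms_b),
                "supporting_sentences": [
                    {"doc_id": s.doc_id, "sentence_index": s.sentence_index, "text": s.text}
                    for s in r.supporting_sentences
                ],
                "source_kb_a": r.source_kb_a,
                "source_kb_b": r.source_kb_b,
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")
    return path


def read_records_jsonl(path: str | Path) -> list[RelationRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            records.append(
                RelationRecord(
                    concept_id_a=obj["concept_id_a"],
                    concept_id_b=obj["concept_id_b"],
                    relation=obj["relation"],
                    class_a=obj["class_a"],
                    class_b=obj["class_b"],
                    name_a=obj["name_a"],
                    name_b=obj["name_b"],
                    synonyms_a=tuple(obj["synonyms_a"]),
                    synonyms_b=tuple(obj["synonyms_b"]),
                    supporting_sentences=tuple(
                        SupportingSentence(s["doc_id"], s["sentence_index"], s["text"])
                        for s in obj["supporting_sentences"]
                    ),
                    source_kb_a=obj.get("source_kb_a", ""),
                    source_kb_b=obj.get("source_kb_b", ""),
                )
            )
    return records


RECORD_TSV_COLUMNS = (
    "concept_id_a",
    "name_a",
    "synonyms_a",
    "concept_id_b",
    "name_b",
    "synonyms_b",
    "relation",
    "support",
    "supporting_sentences",
)


def write_records_tsv(records: Sequence[RelationRecord], path: str | Path) -> Path:
    """Flat TSV export with ";"-joined synonym and sentence fields."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RECORD_TSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.concept_id_a,
                    r.name_a,
                    ";".join(r.synonyms_a),
                    r.concept_id_b,
                    r.name_b,
                    ";".join(r.synonyms_b),
                    r.relation,
                    r.support,
                    ";".join(
                        f"{s.doc_id}:{s.sentence_index}:{s.text}"
                        for s in r.supporting_sentences
                    ),
                ]
            )
    return path
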