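"""Bundled example dataset: relations around the "heart failure" entity.

A small curated set of 11 food/chemical-to-disease relations reported in
cardiovascular literature abstracts, each with its supporting sentences.
It provides a realistic worked example for the aggregation, knowledge
graph, and evaluation stages without any corpus processing: the classic
neighborhood view of the resulting graph is a 12-node star around the
heart-failure node (4 CAUSE and 7 TREAT edges).
"""

from __future__ import annotations

import csv
from importlib import resources

from relmine.aggregation import RelationRecord, SupportingSentence

HEART_FAILURE_CONCEPT_ID = "dis:heart-failure"

_SOURCE_KB = {"FOOD": "UMLS", "CHEMICAL": "PubChem", "DISEASE": "DiseaseOntology"}


def load_heart_failure_example() -> list[RelationRecord]:
    """Load the bundled heart-failure relation records.

    Rows sharing (concept_id, relation) merge into one record whose
    supporting sentences accumulate in file order; every record's B-side
    is the heart-failure disease concept.
    """
    path = resources.files("relmine.data") / "heart_failure_relations.tsv"
    groups: dict[tuple, dict] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["concept_id"], HEART_FAILURE_CONCEPT_ID, row["relation"])
            g = groups.setdefault(
                key,
                {"name": row["name"], "class_a": row["entity_class"], "sentences": []},
            )
            g["sentences"].append(SupportingSentence(row["doc_id"], 0, row["sentence"]))
    records = []
    for key in sorted(groups):
        g = groups[key]
        records.append(
            RelationRecord(
                concept_id_a=key[0],
                concept_id_b=key[1],
                relation=key[2],
                class_a=g["class_a"],
                class_b="DISEASE",
                name_a=g["name"],
                name_b="heart failure",
                synonyms_a=(g["name"],),
                synonyms_b=("heart failure",),
                supporting_sentences=tuple(g["sentences"]),
                source_kb_a=_SOURCE_KB[g["class_a"]],
                source_kb_b=_SOURCE_KB["DISEASE"],
            )
        )
    return records
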