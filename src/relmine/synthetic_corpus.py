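"""Synthetic corpora with planted relations and known ground truth.

The generator emulates the inputs the real pipeline consumes: RRF-dialect
lexicon tables, abstracts in which food/chemical/disease relations are
planted through cue-phrase sentence templates (mixed with objective,
hypothesis, method and filler distractor sentences), and expert
annotation files drawn with known correctness probabilities. Entity
names are nonsense words with class-specific suffixes, so they are
disjoint across classes and can never leak into template or filler text.

All randomness flows from the single integer seed in
:class:`SyntheticSpec` through one ``random.Random`` generator, so a
given (spec, seed) always reproduces byte-identical fixtures.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Sequence

from relmine.aggregation import RelationRecord
from relmine.corpus_io import Corpus, Document
from relmine.errors import ConfigurationError
from relmine.evaluation import AnnotationRecord
from relmine.relation_ensemble import PatternClassifier

#: The five relation kinds a corpus can plant: (class_a, class_b, relation).
RELATION_KINDS = (
    ("FOOD", "DISEASE", "CAUSE"),
    ("FOOD", "DISEASE", "TREAT"),
    ("CHEMICAL", "DISEASE", "CAUSE"),
    ("CHEMICAL", "DISEASE", "TREAT"),
    ("FOOD", "CHEMICAL", "CONTAINS"),
)

#: Cue-phrased sentence skeletons per relation. Every template's cue is
#: recognized by the default pattern classifiers for its relation and by
#: no other relation's classifiers; slots are never sentence-initial so
#: planted surfaces keep their lexicon casing.
DEFAULT_TEMPLATES: dict[str, tuple[str, ...]] = {
    "CAUSE": (
        "High intake of {a} aggravates {b} in older adults.",
        "Regular consumption of {a} is associated with an elevated risk of {b}.",
        "Dietary exposure to {a} can lead to {b}.",
    ),
    "TREAT": (
        "Daily intake of {a} prevents {b} in most patients.",
        "Supplementation with {a} protects against {b}.",
        "Clinicians report that {a} is used to treat {b}.",
    ),
    "CONTAINS": (
        "Portions of {a} contain substantial amounts of {b}.",
        "Nutrient profiling shows that {a} is a rich source of {b}.",
    ),
}

#: Entity-free distractor sentences carrying rhetorical-role cues.
DISTRACTOR_SENTENCES = {
    "OBJECTIVE": (
        "We aimed to characterize dietary patterns in a population cohort.",
        "The objective of this study was to map nutritional exposures.",
    ),
    "HYPOTHESIS": (
        "We hypothesized that dietary composition modulates disease progression.",
        "It was hypothesized that nutrient timing alters metabolic outcomes.",
    ),
    "METHOD": (
        "A cross-sectional survey was performed over two years.",
        "Dietary recall interviews were conducted at baseline.",
    ),
}

#: Entity-free FACT-role filler (no cues, no lexicon names).
FILLER_SENTENCES = (
    "The findings broaden current understanding of population nutrition.",
    "These observations align with earlier cohort summaries.",
    "Overall dietary quality varied widely between participants.",
)

_SYLLABLES = ("ba", "dor", "fen", "gal", "lim", "mor", "nek", "pol", "ras", "tul", "ved", "zan", "kel", "sor", "vab", "qui")
_CLASS_SUFFIXES = {
    "FOOD": ("berry", "root", "bean", "melon", "grain"),
    "CHEMICAL": ("ine", "ol", "ate", "amin"),
    "DISEASE": ("itis", "osis", "emia", "opathy"),
}
_SYNONYM_MODIFIERS = {
    "FOOD": ("fresh", "dried", "whole"),
    "CHEMICAL": ("purified", "total", "free"),
    "DISEASE": ("chronic", "acute", "severe"),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; the seed is mandatory.

    Defaults describe a small literature slice: 200 abstracts, a few
    dozen concepts per class with 1-3 synonyms each, 8 distinct plantable
    relations per relation kind recurring across documents (so
    multi-support records arise), half of the abstracts opening with an
    objective/hypothesis/method sentence, and noise-free classifiers.
    """

    seed: int
    n_documents: int = 200
    n_food: int = 12
    n_chemical: int = 10
    n_disease: int = 8
    food_names: Sequence[str] | None = None
    chemical_names: Sequence[str] | None = None
    disease_names: Sequence[str] | None = None
    max_synonyms: int = 3
    n_relations_per_kind: int = 8
    relation_probabilities: dict = field(
        default_factory=lambda: {kind: 1.0 / len(RELATION_KINDS) for kind in RELATION_KINDS}
    )
    max_facts_per_document: int = 3
    distractor_rate: float = 0.5
    filler_rate: float = 0.4
    classifier_noise_rate: float = 0.0
    plant_in_hypothesis: bool = False
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        for p in (self.distractor_rate, self.filler_rate, self.classifier_noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        for p in self.relation_probabilities.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("relation probabilities must lie in [0, 1]")
        for kind, p in self.relation_probabilities.items():
            if p > 0.0 and not self.templates.get(kind[2]):
                raise ConfigurationError(f"no templates for relation {kind[2]}")


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact end-to-end comparison."""

    #: (concept_id_a, concept_id_b, relation) -> list of (doc_id, sentence_index, text)
    triples: dict = field(default_factory=dict)
    #: (doc_id, sentence_index) -> intended rhetorical role
    roles: dict = field(default_factory=dict)
    #: entity class -> concept_id -> tuple of synonyms
    concepts: dict = field(default_factory=dict)

    def key_support_map(self) -> dict:
        """Planted keys mapped to their carrying-sentence address sets."""
        return {
            key: {(doc_id, idx) for doc_id, idx, _ in sentences}
            for key, sentences in self.triples.items()
        }


def _make_names(rng: Random, n: int, entity_class: str, taken: set) -> list[str]:
    names = []
    suffixes = _CLASS_SUFFIXES[entity_class]
    while len(names) < n:
        stem = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
        name = stem + rng.choice(suffixes)
        if name not in taken:
            taken.add(name)
            names.append(name)
    return names


def _build_concepts(spec: SyntheticSpec) -> dict:
    """Deterministic concept tables: class -> concept_id -> synonyms."""
    rng = Random(spec.seed)
    taken: set = set()
    provided = {
        "FOOD": spec.food_names,
        "CHEMICAL": spec.chemical_names,
        "DISEASE": spec.disease_names,
    }
    counts = {"FOOD": spec.n_food, "CHEMICAL": spec.n_chemical, "DISEASE": spec.n_disease}
    prefixes = {"FOOD": "C1", "CHEMICAL": "C2", "DISEASE": "C3"}
    concepts: dict = {}
    for cls in ("FOOD", "CHEMICAL", "DISEASE"):
        if provided[cls] is not None:
            names = list(provided[cls])
            for name in names:
                if name in taken:
                    raise ConfigurationError(f"name {name!r} appears in more than one class")
                taken.add(name)
        else:
            names = _make_names(rng, counts[cls], cls, taken)
        table = {}
        for i, name in enumerate(names):
            cid = f"{prefixes[cls]}{i:04d}"
            synonyms = [name]
            for modifier in rng.sample(
                _SYNONYM_MODIFIERS[cls], rng.randint(0, min(spec.max_synonyms, 3) - 1)
            ):
                synonyms.append(f"{modifier} {name}")
            table[cid] = tuple(synonyms)
        concepts[cls] = table
    return concepts


_SEMANTIC_TYPES = {"FOOD": "Food", "CHEMICAL": "Organic Chemical", "DISEASE": "Disease or Syndrome"}


@dataclass
class LexiconFixture:
    mrsty_path: Path
    mrconso_path: Path
    class_lexicons: dict  # entity class -> TSV path
    concepts: dict  # entity class -> concept_id -> synonyms


def generate_lexicon_files(spec: SyntheticSpec, outdir: str | Path) -> LexiconFixture:
    """Write RRF-dialect MRSTY/MRCONSO fixtures plus per-class lexicon TSVs.

    Every synthetic concept of every class is present in both tables (so
    the semantic-type filter is meaningfully exercised), with 1-3 English
    synonyms each and a non-English row for every third concept. Output is
    deterministic given the spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    concepts = _build_concepts(spec)
    mrsty_path = outdir / "MRSTY.RRF"
    mrconso_path = outdir / "MRCONSO.RRF"
    with open(mrsty_path, "w", encoding="utf-8", newline="\n") as fh:
        for cls in ("FOOD", "CHEMICAL", "DISEASE"):
            for cid in sorted(concepts[cls]):
                fh.write(f"{cid}|T000|A0.0|{_SEMANTIC_TYPES[cls]}|AT0|0|\n")
    with open(mrconso_path, "w", encoding="utf-8", newline="\n") as fh:
        for cls in ("FOOD", "CHEMICAL", "DISEASE"):
            for k, cid in enumerate(sorted(concepts[cls])):
                for surface in concepts[cls][cid]:
                    row = [""] * 16
                    row[0], row[1], row[11], row[14] = cid, "ENG", "SYNKB", surface
                    fh.write("|".join(row) + "|\n")
                if k % 3 == 0:
                    row = [""] * 16
                    row[0], row[1], row[11], row[14] = cid, "SPA", "SYNKB", concepts[cls][cid][0] + " es"
                    fh.write("|".join(row) + "|\n")
    class_lexicons = {}
    for cls in ("FOOD", "CHEMICAL", "DISEASE"):
        path = outdir / f"{cls.lower()}_lexicon.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for cid in sorted(concepts[cls]):
                for surface in concepts[cls][cid]:
                    fh.write(f"{cid}\t{surface}\n")
        class_lexicons[cls] = path
    return LexiconFixture(mrsty_path, mrconso_path, class_lexicons, concepts)


def _choose_kind(rng: Random, probabilities: dict) -> tuple:
    kinds = [k for k in RELATION_KINDS if probabilities.get(k, 0.0) > 0.0]
    weights = [probabilities[k] for k in kinds]
    return rng.choices(kinds, weights=weights, k=1)[0]


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Generate abstracts with planted relations and their ground truth.

    Each abstract holds an optional role-cue distractor sentence, one to
    ``max_facts_per_document`` fact sentences each instantiating one
    planted triple (slots filled with uniformly chosen synonyms, so
    synonym-union aggregation is exercised), and optional entity-free
    filler. Triples are drawn from a fixed pool per relation kind, so
    relations recur across documents and accumulate support. With
    ``plant_in_hypothesis`` the fact sentences are wrapped in a
    hypothesis cue instead, which downstream role filtering must reject.
    """
    rng = Random(spec.seed + 1)
    concepts = _build_concepts(spec)
    pools: dict[tuple, list] = {}
    for kind in RELATION_KINDS:
        cls_a, cls_b, relation = kind
        if spec.relation_probabilities.get(kind, 0.0) <= 0.0:
            continue
        if not spec.templates.get(relation):
            raise ConfigurationError(f"no templates for relation {relation}")
        pairs = [
            (a, b)
            for a in sorted(concepts[cls_a])
            for b in sorted(concepts[cls_b])
        ]
        rng.shuffle(pairs)
        pools[kind] = pairs[: spec.n_relations_per_kind]
    truth = GroundTruth(concepts=concepts)
    documents = []
    for d in range(spec.n_documents):
        doc_id = f"SYN{d:05d}"
        sentences: list[tuple[str, str]] = []  # (text, role)
        if rng.random() < spec.distractor_rate:
            role = rng.choice(("OBJECTIVE", "HYPOTHESIS", "METHOD"))
            sentences.append((rng.choice(DISTRACTOR_SENTENCES[role]), role))
        planted_here = []
        for _ in range(rng.randint(1, spec.max_facts_per_document)):
            kind = _choose_kind(rng, spec.relation_probabilities)
            cls_a, cls_b, relation = kind
            cid_a, cid_b = rng.choice(pools[kind])
            surface_a = rng.choice(concepts[cls_a][cid_a])
            surface_b = rng.choice(concepts[cls_b][cid_b])
            template = rng.choice(spec.templates[relation])
            text = template.format(a=surface_a, b=surface_b)
            role = "FACT"
            if spec.plant_in_hypothesis:
                text = "We hypothesized that " + text[0].lower() + text[1:]
                role = "HYPOTHESIS"
            sentences.append((text, role))
            planted_here.append(((cid_a, cid_b, relation), len(sentences) - 1, text))
        if rng.random() < spec.filler_rate:
            sentences.append((rng.choice(FILLER_SENTENCES), "FACT"))
        abstract = " ".join(text for text, _ in sentences)
        documents.append(Document(doc_id=doc_id, title=f"Synthetic abstract {d}", abstract=abstract))
        for idx, (_, role) in enumerate(sentences):
            truth.roles[(doc_id, idx)] = role
        if not spec.plant_in_hypothesis:
            for key, idx, text in planted_here:
                entry = truth.triples.setdefault(key, [])
                if not any(a == doc_id and b == idx for a, b, _ in entry):
                    entry.append((doc_id, idx, text))
    return Corpus(documents), truth


def _uniform_from_hash(*parts: object) -> float:
    digest = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2.0**64


def make_mock_classifier(relation: str) -> PatternClassifier:
    """Noise-free classifier that reads the planted template cues."""
    return PatternClassifier(relation, name=f"mock-{relation.lower()}")


class NoisyClassifier:
    """Ground-truth classifier whose output is flipped with a fixed
    probability, independently per (seed, text).

    Flips derive from a hash of (seed, relation, text), so predictions
    are deterministic given the text while distinct seeds give
    independent classifier instances.
    """

    def __init__(self, relation: str, flip_probability: float, seed: int):
        if not 0.0 <= flip_probability <= 1.0:
            raise ConfigurationError("flip_probability must lie in [0, 1]")
        self.relation_trained_for = relation
        self.flip_probability = flip_probability
        self.seed = seed
        self.name = f"noisy-{relation.lower()}-{seed}"
        self._base = make_mock_classifier(relation)

    def predict(self, masked_text: str) -> int:
        vote = self._base.predict(masked_text)
        if _uniform_from_hash(self.seed, self.relation_trained_for, masked_text) < self.flip_probability:
            vote ^= 1
        return vote


def make_noisy_classifier(relation: str, flip_probability: float, seed: int) -> NoisyClassifier:
    return NoisyClassifier(relation, flip_probability, seed)


def expected_cause_assignment_rate(
    flip_probability: float, n_models: int = 4, min_for: int = 3, max_against: int = 1
) -> float:
    """Closed-form assignment rate for a true-CAUSE pair under the
    cause/treat voting rule with per-model flip probability p:
    P(Bin(n, 1-p) >= min_for) * P(Bin(n, p) <= max_against)."""
    p = flip_probability

    def binom_tail(n: int, q: int, prob: float, at_least: bool) -> float:
        ks = range(q, n + 1) if at_least else range(0, q + 1)
        return sum(math.comb(n, k) * prob**k * (1 - prob) ** (n - k) for k in ks)

    return binom_tail(n_models, min_for, 1 - p, True) * binom_tail(n_models, max_against, p, False)


def simulate_noisy_ensemble(
    n_pairs: int,
    flip_probability: float,
    seed: int,
    true_relation: str = "CAUSE",
    n_models: int = 4,
    min_for: int = 3,
    max_against: int = 1,
) -> dict:
    """Monte-Carlo check of the voting scheme under classifier noise.

    Simulates ``n_pairs`` masked sentences that truly express
    ``true_relation``, votes with ``n_models`` noisy cause and treat
    classifiers each, and tallies the voting outcomes. Returns the
    empirical assignment rate of the true relation alongside the closed
    form for comparison.
    """
    from relmine.relation_ensemble import vote_cause_treat

    cue = {"CAUSE": "aggravates", "TREAT": "prevents"}[true_relation]
    cause_bank = [make_noisy_classifier("CAUSE", flip_probability, seed * 100 + i) for i in range(n_models)]
    treat_bank = [make_noisy_classifier("TREAT", flip_probability, seed * 100 + n_models + i) for i in range(n_models)]
    counts = {"CAUSE": 0, "TREAT": 0, "DISCARD": 0}
    for i in range(n_pairs):
        text = f"@FOOD$ {cue} @DISEASE$ in cohort {i}."
        cause_votes = tuple(c.predict(text) for c in cause_bank)
        treat_votes = tuple(t.predict(text) for t in treat_bank)
        outcome = vote_cause_treat(
            cause_votes, treat_votes, n_models=n_models, min_for=min_for, max_against=max_against
        )
        counts[outcome] += 1
    empirical = counts[true_relation] / n_pairs
    expected = expected_cause_assignment_rate(flip_probability, n_models, min_for, max_against)
    return {
        "counts": counts,
        "empirical_rate": empirical,
        "expected_rate": expected,
        "n_pairs": n_pairs,
        "standard_error": math.sqrt(expected * (1 - expected) / n_pairs),
    }


def generate_annotations(
    records: Sequence[RelationRecord],
    seed: int,
    base_correctness: float = 0.6,
    support_slope: float = 0.2,
    annotator_ids: Sequence[str] = ("annotator-1",),
    coverage: float = 1.0,
) -> tuple[list[AnnotationRecord], dict]:
    """Draw synthetic expert annotations with known generating precision.

    A record with support s is marked correct with probability
    min(1, base_correctness + support_slope * (s - 1)), independently per
    annotator; a fraction ``coverage`` of records (rounded down, chosen
    at random) is annotated. Returns the annotations and the generating
    probability per record key.
    """
    rng = Random(seed)
    records = list(records)
    n_covered = int(len(records) * coverage)
    covered_idx = sorted(rng.sample(range(len(records)), n_covered))
    probabilities = {}
    annotations = []
    for i in covered_idx:
        r = records[i]
        p = min(1.0, base_correctness + support_slope * (r.support - 1))
        probabilities[r.key] = p
        for annotator in annotator_ids:
            annotations.append(
                AnnotationRecord(
                    concept_id_a=r.concept_id_a,
                    concept_id_b=r.concept_id_b,
                    relation=r.relation,
                    indicator=int(rng.random() < p),
                    annotator_id=annotator,
                )
            )
    return annotations, probabilities
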