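"""Ensemble voting over pluggable binary relation classifiers.

Two voting schemes are implemented. For cause/treat schemas, two banks
of four models each vote on the masked sentence; a relation is assigned
only when at least ``min_for`` (default 3) of its own models are
positive AND at most ``max_against`` (default 1) of the opposing
relation's models are positive — otherwise the pair is discarded. For
the food-chemical schema a single bank of three models votes and
CONTAINS is assigned on a simple majority (at least 2 of 3). Both
thresholds are parameterized so the schemes can be studied in
simulation, with defaults reproducing the reference configuration.

Transformer-backed classifiers plug in through the
:class:`RelationClassifier` contract; the bundled default is a
deterministic cue-phrase pattern classifier so the full pipeline runs
with no model weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import yaml

from relmine.candidate_gen import CandidatePair, RELATION_LABELS
from relmine.errors import ConfigurationError, PipelineStageError

#: Outcome sentinel for pairs on which no relation is assigned.
DISCARD = "DISCARD"


@dataclass(frozen=True)
class VoteVector:
    """Per-classifier binary predictions for one candidate pair.

    Cause/treat schemas fill ``cause_votes`` and ``treat_votes`` (length
    4 each in the default configuration); the contains schema fills
    ``contains_votes`` (length 3).
    """

    cause_votes: tuple = ()
    treat_votes: tuple = ()
    contains_votes: tuple = ()

    def __post_init__(self) -> None:
        for votes in (self.cause_votes, self.treat_votes, self.contains_votes):
            if any(v not in (0, 1) for v in votes):
                raise ConfigurationError(f"votes must be binary, got {votes}")


@dataclass(frozen=True)
class SentenceRelation:
    """A relation asserted by one sentence for one candidate pair."""

    pair: CandidatePair
    label: str
    votes: VoteVector


@runtime_checkable
class RelationClassifier(Protocol):
    """Contract for binary per-relation classifiers.

    ``predict`` maps a masked sentence text to 0/1 and must be
    deterministic given the text (stochastic implementations take a
    seed at construction).
    """

    relation_trained_for: str

    def predict(self, masked_text: str) -> int: ...


#: Default cue-phrase table for the bundled pattern classifier. Phrases
#: are matched casefolded as substrings of the masked sentence.
DEFAULT_CUE_TABLE: dict[str, tuple[str, ...]] = {
    "CAUSE": (
        "aggravates",
        "aggravate",
        "exacerbates",
        "induces",
        "induce",
        "elevated risk of",
        "increased risk of",
        "increases the risk of",
        "can lead to",
        "leads to",
        "causes",
        "contributes to the development of",
        "associated with an elevated risk",
    ),
    "TREAT": (
        "prevents",
        "prevent",
        "alleviates",
        "is used to treat",
        "used for treating",
        "treatment for",
        "protects against",
        "protective against",
        "beneficial role",
        "beneficial effect",
        "reduces the risk of",
        "recommended for preventing",
    ),
    "CONTAINS": (
        "contains",
        "contain",
        "rich source of",
        "is abundant in",
        "substantial amounts of",
        "high amounts of",
        "is composed of",
        "composition includes",
    ),
}


class PatternClassifier:
    """Deterministic cue-phrase relation classifier.

    Predicts 1 when any configured cue phrase for its relation occurs in
    the masked text. Ships as the default ensemble member so the
    pipeline is runnable and auditable offline.
    """

    def __init__(
        self,
        relation_trained_for: str,
        cues: Sequence[str] | None = None,
        name: str = "pattern",
    ):
        if relation_trained_for not in RELATION_LABELS:
            raise ConfigurationError(f"unknown relation {relation_trained_for!r}")
        self.relation_trained_for = relation_trained_for
        self.cues = tuple(
            c.casefold() for c in (cues if cues is not None else DEFAULT_CUE_TABLE[relation_trained_for])
        )
        self.name = name

    def predict(self, masked_text: str) -> int:
        text = masked_text.casefold()
        return int(any(c in text for c in self.cues))


def vote_cause_treat(
    cause_votes: Sequence[int],
    treat_votes: Sequence[int],
    *,
    n_models: int = 4,
    min_for: int = 3,
    max_against: int = 1,
) -> str:
    """Combine cause/treat bank votes into CAUSE, TREAT or DISCARD.

    CAUSE requires at least ``min_for`` positive cause votes and at most
    ``max_against`` positive treat votes; TREAT is the mirror image; any
    other combination is discarded. The two conditions are mutually
    exclusive whenever ``min_for > max_against``.
    """
    if len(cause_votes) != n_models or len(treat_votes) != n_models:
        raise ConfigurationError(
            f"expected {n_models}+{n_models} votes, got {len(cause_votes)}+{len(treat_votes)}"
        )
    cause, treat = sum(cause_votes), sum(treat_votes)
    if cause >= min_for and treat <= max_against:
        return "CAUSE"
    if treat >= min_for and cause <= max_against:
        return "TREAT"
    return DISCARD


def vote_contains(votes: Sequence[int], *, n_models: int = 3, min_for: int = 2) -> str:
    """Majority vote for the CONTAINS relation: assigned iff at least
    ``min_for`` of the ``n_models`` votes are positive."""
    if len(votes) != n_models:
        raise ConfigurationError(f"expected {n_models} votes, got {len(votes)}")
    return "CONTAINS" if sum(votes) >= min_for else DISCARD


@dataclass
class CauseTreatEnsemble:
    """Two banks of classifiers voting on cause/treat schemas."""

    cause_classifiers: tuple
    treat_classifiers: tuple
    min_for: int = 3
    max_against: int = 1

    def __post_init__(self) -> None:
        if len(self.cause_classifiers) != len(self.treat_classifiers):
            raise ConfigurationError("cause and treat banks must have equal size")
        for clf in self.cause_classifiers:
            if clf.relation_trained_for != "CAUSE":
                raise ConfigurationError("cause bank holds a non-CAUSE classifier")
        for clf in self.treat_classifiers:
            if clf.relation_trained_for != "TREAT":
                raise ConfigurationError("treat bank holds a non-TREAT classifier")


@dataclass
class ContainsEnsemble:
    """A single bank of classifiers voting on the contains schema."""

    classifiers: tuple
    min_for: int = 2

    def __post_init__(self) -> None:
        for clf in self.classifiers:
            if clf.relation_trained_for != "CONTAINS":
                raise ConfigurationError("contains bank holds a non-CONTAINS classifier")


Ensemble = CauseTreatEnsemble | ContainsEnsemble


def default_ensemble(schema_relations: frozenset) -> Ensemble:
    """Pattern-classifier ensemble in the reference configuration:
    4 cause + 4 treat models, or 3 contains models."""
    if schema_relations == frozenset({"CONTAINS"}):
        return ContainsEnsemble(
            tuple(PatternClassifier("CONTAINS", name=f"pattern-contains-{i}") for i in range(3))
        )
    return CauseTreatEnsemble(
        tuple(PatternClassifier("CAUSE", name=f"pattern-cause-{i}") for i in range(4)),
        tuple(PatternClassifier("TREAT", name=f"pattern-treat-{i}") for i in range(4)),
    )


def _predict_bank(classifiers: Iterable, text: str, pair: CandidatePair) -> tuple:
    votes = []
    for clf in classifiers:
        try:
            votes.append(int(clf.predict(text)))
        except Exception as exc:  # noqa: BLE001 - re-raised with pair address
            raise PipelineStageError(
                "relation_ensemble",
                f"classifier {getattr(clf, 'name', clf)!r} failed on pair "
                f"({pair.sentence.doc_id}, {pair.sentence.index}): {exc}",
            ) from exc
    return tuple(votes)


def classify_pair(pair: CandidatePair, ensemble: Ensemble) -> SentenceRelation | None:
    """Run the ensemble on one masked pair and apply the voting rule.

    Returns the assigned :class:`SentenceRelation`, or ``None`` when the
    votes do not satisfy any assignment rule (the pair is discarded;
    discarding is per-pair, so other pairs in the same sentence are
    unaffected).
    """
    relation, votes = classify_pair_with_votes(pair, ensemble)
    if relation == DISCARD:
        return None
    label = relation
    allowed = {"CAUSE", "TREAT"} if isinstance(ensemble, CauseTreatEnsemble) else {"CONTAINS"}
    if label not in allowed:
        raise ConfigurationError(f"label {label} not permitted by ensemble")
    return SentenceRelation(pair=pair, label=label, votes=votes)


def classify_pair_with_votes(
    pair: CandidatePair, ensemble: Ensemble
) -> tuple[str, VoteVector]:
    """As :func:`classify_pair`, but always returns the outcome and the
    full vote vector (for audit logging)."""
    text = pair.masked_text
    if isinstance(ensemble, CauseTreatEnsemble):
        cause = _predict_bank(ensemble.cause_classifiers, text, pair)
        treat = _predict_bank(ensemble.treat_classifiers, text, pair)
        outcome = vote_cause_treat(
            cause,
            treat,
            n_models=len(cause),
            min_for=ensemble.min_for,
            max_against=ensemble.max_against,
        )
        return outcome, VoteVector(cause_votes=cause, treat_votes=treat)
    if isinstance(ensemble, ContainsEnsemble):
        votes = _predict_bank(ensemble.classifiers, text, pair)
        outcome = vote_contains(votes, n_models=len(votes), min_for=ensemble.min_for)
        return outcome, VoteVector(contains_votes=votes)
    raise ConfigurationError(f"unknown ensemble type {type(ensemble).__name__}")


def load_ensemble_config(path: str | Path) -> dict[str, Ensemble]:
    """Load pattern ensembles from a YAML configuration file.

    Layout::

        cause_treat:
          min_for: 3
          max_against: 1
          cause: [{name: c0, cues: ["causes", ...]}, ...]
          treat: [{name: t0, cues: ["treats", ...]}, ...]
        contains:
          min_for: 2
          models: [{name: m0, cues: ["contains", ...]}, ...]

    Classifier order follows file order so vote vectors are
    reproducible. Returns ensembles keyed "cause_treat" and "contains";
    missing sections fall back to the defaults.
    """
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict[str, Ensemble] = {}
    ct = cfg.get("cause_treat")
    if ct:
        out["cause_treat"] = CauseTreatEnsemble(
            tuple(
                PatternClassifier("CAUSE", cues=m.get("cues"), name=m.get("name", f"cause-{i}"))
                for i, m in enumerate(ct.get("cause", []))
            ),
            tuple(
                PatternClassifier("TREAT", cues=m.get("cues"), name=m.get("name", f"treat-{i}"))
                for i, m in enumerate(ct.get("treat", []))
            ),
            min_for=int(ct.get("min_for", 3)),
            max_against=int(ct.get("max_against", 1)),
        )
    else:
        out["cause_treat"] = default_ensemble(frozenset({"CAUSE", "TREAT"}))
    co = cfg.get("contains")
    if co:
        out["contains"] = ContainsEnsemble(
            tuple(
                PatternClassifier("CONTAINS", cues=m.get("cues"), name=m.get("name", f"contains-{i}"))
                for i, m in enumerate(co.get("models", []))
            ),
            min_for=int(co.get("min_for", 2)),
        )
    else:
        out["contains"] = default_ensemble(frozenset({"CONTAINS"}))
    return out


VOTE_LOG_COLUMNS = (
    "doc_id",
    "sentence_index",
    "schema",
    "mention_a",
    "concept_id_a",
    "mention_b",
    "concept_id_b",
    "cause_votes",
    "treat_votes",
    "contains_votes",
    "outcome",
)


def write_vote_log(
    rows: Iterable[tuple[CandidatePair, str, str, VoteVector]], path: str | Path
) -> Path:
    """Write the per-pair vote audit log as TSV.

    Each row is (pair, schema name, outcome, votes); vote tuples are
    serialized as comma-joined binaries.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VOTE_LOG_COLUMNS)
        for pair, schema_name, outcome, votes in rows:
            writer.writerow(
                [
                    pair.sentence.doc_id,
                    pair.sentence.index,
                    schema_name,
                    pair.mention_a.surface,
                    pair.mention_a.concept_id,
                    pair.mention_b.surface,
                    pair.mention_b.concept_id,
                    ",".join(map(str, votes.cause_votes)),
                    ",".join(map(str, votes.treat_votes)),
                    ",".join(map(str, votes.contains_votes)),
                    outcome,
                ]
            )
    return path
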