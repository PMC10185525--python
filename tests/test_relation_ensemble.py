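from itertools import product

import pytest

from conftest import make_sentence
from relmine.candidate_gen import FOODCHEM_SCHEMA, FOODIS_SCHEMA, enumerate_candidate_pairs
from relmine.errors import ConfigurationError, PipelineStageError
from relmine.lexicon_ner import EntityMention
from relmine.relation_ensemble import (
    DISCARD,
    CauseTreatEnsemble,
    ContainsEnsemble,
    PatternClassifier,
    VoteVector,
    classify_pair,
    classify_pair_with_votes,
    default_ensemble,
    load_ensemble_config,
    vote_cause_treat,
    vote_contains,
)


def oracle_cause_treat(cause, treat):
    """Independent restatement of the assignment rule, by enumeration."""
    if sum(cause) >= 3 and sum(treat) <= 1:
        return "CAUSE"
    if sum(treat) >= 3 and sum(cause) <= 1:
        return "TREAT"
    return DISCARD


class TestVoteCauseTreat:
    def test_unanimous_cause(self):
        assert vote_cause_treat((1, 1, 1, 1), (0, 0, 0, 0)) == "CAUSE"

    def test_split_votes_discard(self):
        assert vote_cause_treat((1, 1, 0, 0), (1, 1, 0, 0)) == DISCARD

    def test_three_for_one_against_boundary(self):
        assert vote_cause_treat((1, 1, 1, 0), (1, 0, 0, 0)) == "CAUSE"
        assert vote_cause_treat((1, 1, 1, 0), (1, 1, 0, 0)) == DISCARD
        assert vote_cause_treat((0, 1, 0, 0), (1, 1, 1, 1)) == "TREAT"

    def test_exhaustive_enumeration_matches_oracle_and_counts(self):
        counts = {"CAUSE": 0, "TREAT": 0, DISCARD: 0}
        for votes in product((0, 1), repeat=8):
            cause, treat = votes[:4], votes[4:]
            outcome = vote_cause_treat(cause, treat)
            assert outcome == oracle_cause_treat(cause, treat)
            counts[outcome] += 1
        # combinatorial closed form: (C(4,3)+C(4,4)) * (C(4,0)+C(4,1)) = 5*5
        assert counts == {"CAUSE": 25, "TREAT": 25, DISCARD: 206}

    def test_mutual_exclusivity_over_all_vectors(self):
        for votes in product((0, 1), repeat=8):
            cause, treat = votes[:4], votes[4:]
            cause_fires = sum(cause) >= 3 and sum(treat) <= 1
            treat_fires = sum(treat) >= 3 and sum(cause) <= 1
            assert not (cause_fires and treat_fires)

    def test_monotonicity_of_single_vote_flips(self):
        """Flipping one vote for relation R from 0 to 1 never moves the
        outcome away from R."""
        for votes in product((0, 1), repeat=8):
            cause, treat = list(votes[:4]), list(votes[4:])
            before = vote_cause_treat(tuple(cause), tuple(treat))
            for i in range(4):
                if cause[i] == 0:
                    flipped = cause.copy()
                    flipped[i] = 1
                    after = vote_cause_treat(tuple(flipped), tuple(treat))
                    if before == "CAUSE":
                        assert after == "CAUSE"
                if treat[i] == 0:
                    flipped = treat.copy()
                    flipped[i] = 1
                    after = vote_cause_treat(tuple(cause), tuple(flipped))
                    if before == "TREAT":
                        assert after == "TREAT"

    def test_wrong_vector_length_rejected(self):
        with pytest.raises(ConfigurationError):
            vote_cause_treat((1, 1, 1), (0, 0, 0, 0))
        with pytest.raises(ConfigurationError):
            vote_cause_treat((1, 1, 1, 1), (0, 0))


class TestVoteContains:
    def test_majority_assigns(self):
        assert vote_contains((1, 1, 0)) == "CONTAINS"
        assert vote_contains((1, 0, 0)) == DISCARD

    def test_exhaustive_enumeration(self):
        outcomes = [vote_contains(v) for v in product((0, 1), repeat=3)]
        assert outcomes.count("CONTAINS") == 4
        assert outcomes.count(DISCARD) == 4
        for v in product((0, 1), repeat=3):
            assert vote_contains(v) == ("CONTAINS" if sum(v) >= 2 else DISCARD)

    def test_wrong_length_rejected(self):
        with pytest.raises(ConfigurationError):
            vote_contains((1, 1))


def food_disease_pair():
    s = make_sentence("salt aggravates heart failure symptoms")
    a = EntityMention(s.doc_id, s.index, 0, 4, "salt", "FOOD", "C1")
    b = EntityMention(s.doc_id, s.index, 16, 29, "heart failure", "DISEASE", "D1")
    (pair,) = enumerate_candidate_pairs(s, [a, b], FOODIS_SCHEMA, role="FACT")
    return pair


def food_chemical_pair(text="milk contains substantial amounts of calcium"):
    s = make_sentence(text)
    a = EntityMention(s.doc_id, s.index, 0, 4, "milk", "FOOD", "C1")
    start = text.index("calcium")
    b = EntityMention(s.doc_id, s.index, start, start + 7, "calcium", "CHEMICAL", "K1")
    (pair,) = enumerate_candidate_pairs(s, [a, b], FOODCHEM_SCHEMA, role="FACT")
    return pair


class _ConstantClassifier:
    def __init__(self, relation, value):
        self.relation_trained_for = relation
        self.value = value
        self.name = f"const-{value}"

    def predict(self, masked_text):
        return self.value


class _RaisingClassifier:
    relation_trained_for = "CAUSE"
    name = "boom"

    def predict(self, masked_text):
        raise RuntimeError("boom")


class TestClassifyPair:
    def test_pattern_ensemble_assigns_cause_on_cue(self):
        pair = food_disease_pair()
        assert "@FOOD$" in pair.masked_text and "@DISEASE$" in pair.masked_text
        relation = classify_pair(pair, default_ensemble(FOODIS_SCHEMA.relations))
        assert relation is not None
        assert relation.label == "CAUSE"
        assert relation.votes.cause_votes == (1, 1, 1, 1)
        assert relation.votes.treat_votes == (0, 0, 0, 0)

    def test_contains_ensemble_on_food_chemical_pair(self):
        pair = food_chemical_pair()
        relation = classify_pair(pair, default_ensemble(FOODCHEM_SCHEMA.relations))
        assert relation is not None and relation.label == "CONTAINS"

    def test_all_zero_classifiers_discard(self):
        pair = food_disease_pair()
        ensemble = CauseTreatEnsemble(
            tuple(_ConstantClassifier("CAUSE", 0) for _ in range(4)),
            tuple(_ConstantClassifier("TREAT", 0) for _ in range(4)),
        )
        assert classify_pair(pair, ensemble) is None
        outcome, votes = classify_pair_with_votes(pair, ensemble)
        assert outcome == DISCARD
        assert votes.cause_votes == (0, 0, 0, 0)

    def test_classifier_exception_carries_pair_address(self):
        pair = food_disease_pair()
        ensemble = CauseTreatEnsemble(
            (_RaisingClassifier(),) + tuple(_ConstantClassifier("CAUSE", 0) for _ in range(3)),
            tuple(_ConstantClassifier("TREAT", 0) for _ in range(4)),
        )
        with pytest.raises(PipelineStageError, match="doc1"):
            classify_pair(pair, ensemble)

    def test_misfiled_classifier_rejected_at_construction(self):
        with pytest.raises(ConfigurationError):
            CauseTreatEnsemble(
                tuple(_ConstantClassifier("TREAT", 1) for _ in range(4)),
                tuple(_ConstantClassifier("TREAT", 1) for _ in range(4)),
            )

    def test_non_binary_votes_rejected(self):
        with pytest.raises(ConfigurationError):
            VoteVector(cause_votes=(0, 2, 0, 0))


class TestEnsembleConfig:
    def test_yaml_round_trip_preserves_order_and_thresholds(self, tmp_path):
        cfg = tmp_path / "ensemble.yaml"
        cfg.write_text(
            "cause_treat:\n"
            "  min_for: 2\n"
            "  max_against: 0\n"
            "  cause:\n"
            "    - {name: c0, cues: ['provokes']}\n"
            "    - {name: c1, cues: ['provokes', 'worsens']}\n"
            "  treat:\n"
            "    - {name: t0, cues: ['soothes']}\n"
            "    - {name: t1, cues: ['soothes']}\n"
        )
        ensembles = load_ensemble_config(cfg)
        ct = ensembles["cause_treat"]
        assert [c.name for c in ct.cause_classifiers] == ["c0", "c1"]
        assert (ct.min_for, ct.max_against) == (2, 0)
        # defaults fill the missing contains section
        assert isinstance(ensembles["contains"], ContainsEnsemble)
        assert len(ensembles["contains"].classifiers) == 3

    def test_pattern_classifier_unknown_relation_rejected(self):
        with pytest.raises(ConfigurationError):
            PatternClassifier("ASSOCIATES")
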