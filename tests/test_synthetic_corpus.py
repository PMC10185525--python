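import pytest

from relmine import aggregation
from relmine.corpus_io import segment_sentences
from relmine.errors import ConfigurationError
from relmine.lexicon_ner import DictionaryRecognizer, build_food_lexicon, load_lexicon_tsv
from relmine.pipeline import extract_relations
from relmine.synthetic_corpus import (
    DISTRACTOR_SENTENCES,
    FILLER_SENTENCES,
    SyntheticSpec,
    expected_cause_assignment_rate,
    generate_corpus,
    generate_lexicon_files,
    make_mock_classifier,
    make_noisy_classifier,
    simulate_noisy_ensemble,
)


class TestLexiconFixtures:
    def test_rrf_round_trip_recovers_planted_food_concepts(self, tmp_path):
        spec = SyntheticSpec(seed=3, n_documents=5, n_food=5)
        fixture = generate_lexicon_files(spec, tmp_path)
        lexicon = build_food_lexicon(fixture.mrsty_path, fixture.mrconso_path, "Food")
        assert lexicon.concept_ids == set(fixture.concepts["FOOD"])
        planted_surfaces = {
            s for syns in fixture.concepts["FOOD"].values() for s in syns
        }
        assert {e.surface for e in lexicon} == planted_surfaces

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = SyntheticSpec(seed=11, n_documents=5)
        a, b = tmp_path / "a", tmp_path / "b"
        fa = generate_lexicon_files(spec, a)
        fb = generate_lexicon_files(spec, b)
        assert fa.mrsty_path.read_bytes() == fb.mrsty_path.read_bytes()
        assert fa.mrconso_path.read_bytes() == fb.mrconso_path.read_bytes()
        for cls in fa.class_lexicons:
            assert fa.class_lexicons[cls].read_bytes() == fb.class_lexicons[cls].read_bytes()

    def test_name_collision_across_classes_rejected(self, tmp_path):
        spec = SyntheticSpec(seed=1, food_names=["sharedname"], chemical_names=["sharedname"])
        with pytest.raises(ConfigurationError):
            generate_lexicon_files(spec, tmp_path)

    def test_class_disjoint_names(self):
        spec = SyntheticSpec(seed=5)
        corpus, truth = generate_corpus(spec)
        all_names: list[str] = []
        for table in truth.concepts.values():
            for syns in table.values():
                all_names.extend(syns)
        assert len(all_names) == len(set(all_names))


class TestCorpusGeneration:
    def test_determinism(self):
        spec = SyntheticSpec(seed=21, n_documents=30)
        c1, t1 = generate_corpus(spec)
        c2, t2 = generate_corpus(spec)
        assert c1.documents == c2.documents
        assert t1.triples == t2.triples and t1.roles == t2.roles

    def test_planted_sentences_survive_segmentation(self):
        spec = SyntheticSpec(seed=8, n_documents=40)
        corpus, truth = generate_corpus(spec)
        by_doc = {doc.doc_id: segment_sentences(doc) for doc in corpus}
        for key, carriers in truth.triples.items():
            assert carriers, f"planted triple {key} has no carrying sentence"
            for doc_id, idx, text in carriers:
                assert by_doc[doc_id][idx].text == text

    def test_no_leakage_of_concept_names_into_distractors_or_filler(self):
        spec = SyntheticSpec(seed=13)
        _, truth = generate_corpus(spec)
        fixed_text = " ".join(
            [t for group in DISTRACTOR_SENTENCES.values() for t in group]
            + list(FILLER_SENTENCES)
        ).casefold()
        for table in truth.concepts.values():
            for syns in table.values():
                for name in syns:
                    assert name.casefold() not in fixed_text

    def test_multi_support_relations_arise(self):
        spec = SyntheticSpec(seed=2, n_documents=150)
        _, truth = generate_corpus(spec)
        supports = [len(v) for v in truth.triples.values()]
        assert max(supports) >= 2

    def test_roles_recorded_per_sentence(self):
        spec = SyntheticSpec(seed=4, n_documents=20, distractor_rate=1.0)
        corpus, truth = generate_corpus(spec)
        roles = set(truth.roles.values())
        assert "FACT" in roles
        assert roles & {"OBJECTIVE", "HYPOTHESIS", "METHOD"}


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_ground_truth_exactly(
        self, synthetic_world, synthetic_recognizers
    ):
        """Precision = recall = 1.0 against the planted record set, including
        the exact supporting-sentence addresses."""
        _, _, corpus, truth = synthetic_world
        srs, _, counts = extract_relations(
            corpus, synthetic_recognizers, ["foodis", "foodchem", "chemdis"]
        )
        records = aggregation.aggregate_relations(srs)
        got = {
            r.key: {(s.doc_id, s.sentence_index) for s in r.supporting_sentences}
            for r in records
        }
        assert got == truth.key_support_map()
        assert counts["pairs_generated"] == counts["pairs_discarded"] + counts["sentence_relations"]

    def test_synonym_union_matches_planted_synonyms(self, synthetic_world, synthetic_recognizers):
        _, fixture, corpus, truth = synthetic_world
        srs, _, _ = extract_relations(corpus, synthetic_recognizers, ["foodis", "foodchem", "chemdis"])
        for record in aggregation.aggregate_relations(srs):
            cls_a = record.class_a
            planted = set(map(str.casefold, truth.concepts[cls_a][record.concept_id_a]))
            observed = set(map(str.casefold, record.synonyms_a))
            assert observed <= planted

    def test_hypothesis_planting_yields_zero_records(self, tmp_path):
        spec = SyntheticSpec(seed=20240, n_documents=60, plant_in_hypothesis=True)
        fixture = generate_lexicon_files(spec, tmp_path)
        corpus, truth = generate_corpus(spec)
        recognizers = {
            cls: DictionaryRecognizer(load_lexicon_tsv(path), cls)
            for cls, path in fixture.class_lexicons.items()
        }
        srs, _, counts = extract_relations(corpus, recognizers, ["foodis", "foodchem", "chemdis"])
        assert srs == []
        assert counts["pairs_generated"] == 0
        assert truth.triples == {}


class TestNoisyClassifiers:
    def test_zero_flip_equals_mock(self):
        mock = make_mock_classifier("CAUSE")
        noisy = make_noisy_classifier("CAUSE", 0.0, seed=5)
        texts = [f"@FOOD$ aggravates @DISEASE$ case {i}." for i in range(50)]
        assert [noisy.predict(t) for t in texts] == [mock.predict(t) for t in texts]

    def test_full_flip_always_inverts(self):
        mock = make_mock_classifier("TREAT")
        noisy = make_noisy_classifier("TREAT", 1.0, seed=5)
        texts = [f"@FOOD$ prevents @DISEASE$ case {i}." for i in range(50)]
        assert [noisy.predict(t) for t in texts] == [1 - mock.predict(t) for t in texts]

    def test_deterministic_given_text_and_seed(self):
        a = make_noisy_classifier("CAUSE", 0.5, seed=9)
        b = make_noisy_classifier("CAUSE", 0.5, seed=9)
        texts = [f"@FOOD$ induces @DISEASE$ {i}" for i in range(20)]
        assert [a.predict(t) for t in texts] == [b.predict(t) for t in texts]

    def test_closed_form_matches_weighted_enumeration_oracle(self):
        """The analytic assignment rate equals an exhaustive enumeration of
        all 2^8 vote vectors weighted by their probabilities."""
        from itertools import product

        p = 0.2
        total = 0.0
        for votes in product((0, 1), repeat=8):
            cause, treat = votes[:4], votes[4:]
            # true-CAUSE pair: cause votes are 1 unless flipped, treat votes 0 unless flipped
            prob = 1.0
            for v in cause:
                prob *= (1 - p) if v == 1 else p
            for v in treat:
                prob *= p if v == 1 else (1 - p)
            if sum(cause) >= 3 and sum(treat) <= 1:
                total += prob
        assert expected_cause_assignment_rate(p) == pytest.approx(total)

    def test_empirical_rate_within_three_standard_errors(self):
        result = simulate_noisy_ensemble(2000, 0.2, seed=123)
        assert abs(result["empirical_rate"] - result["expected_rate"]) <= 3 * result["standard_error"]

    def test_expected_rate_value(self):
        # P(Bin(4, .8) >= 3) = 0.8192 and P(Bin(4, .2) <= 1) = 0.8192
        assert expected_cause_assignment_rate(0.2) == pytest.approx(0.8192 * 0.8192)


def test_property_random_specs_recover_truth():
    """Noise-free, all-FACT extraction equals ground truth for a sweep of
    random generator configurations."""
    for seed in (101, 202, 303):
        spec = SyntheticSpec(
            seed=seed,
            n_documents=40,
            n_food=6,
            n_chemical=5,
            n_disease=4,
            distractor_rate=0.0,
        )
        corpus, truth = generate_corpus(spec)
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            fixture = generate_lexicon_files(spec, td)
            recognizers = {
                cls: DictionaryRecognizer(load_lexicon_tsv(path), cls)
                for cls, path in fixture.class_lexicons.items()
            }
            srs, _, _ = extract_relations(corpus, recognizers, ["foodis", "foodchem", "chemdis"])
        records = aggregation.aggregate_relations(srs)
        got = {r.key: {(s.doc_id, s.sentence_index) for s in r.supporting_sentences} for r in records}
        assert got == truth.key_support_map()
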