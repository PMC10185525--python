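import random

import pytest

from conftest import make_sentence
from relmine.errors import ContractViolationError
from relmine.lexicon_ner import (
    DictionaryRecognizer,
    Lexicon,
    LexiconEntry,
    build_food_lexicon,
    load_lexicon_tsv,
    match_food_entities,
    normalize_surface,
    recognize_entities,
    resolve_leftmost_longest,
    write_lexicon_tsv,
)


def write_rrf(tmp_path, mrsty_rows, mrconso_rows):
    mrsty = tmp_path / "MRSTY.RRF"
    mrsty.write_text("".join(f"{cui}|T0|A0|{stype}|AT|0|\n" for cui, stype in mrsty_rows))
    mrconso = tmp_path / "MRCONSO.RRF"
    lines = []
    for cui, lang, surface in mrconso_rows:
        row = [""] * 16
        row[0], row[1], row[14] = cui, lang, surface
        lines.append("|".join(row) + "|\n")
    mrconso.write_text("".join(lines))
    return mrsty, mrconso


class TestBuildFoodLexicon:
    def test_two_step_filter_with_case_folding(self, tmp_path):
        mrsty, mrconso = write_rrf(
            tmp_path,
            [("C1", "Food"), ("C2", "Disease or Syndrome")],
            [("C1", "ENG", "milk"), ("C1", "ENG", "Milk"), ("C2", "ENG", "angina")],
        )
        lexicon = build_food_lexicon(mrsty, mrconso)
        assert lexicon.concept_ids == {"C1"}
        assert [e.surface for e in lexicon] == ["milk"]

    def test_empty_semantic_type_table_gives_empty_lexicon(self, tmp_path, caplog):
        mrsty, mrconso = write_rrf(tmp_path, [], [("C1", "ENG", "milk")])
        with caplog.at_level("WARNING"):
            lexicon = build_food_lexicon(mrsty, mrconso)
        assert lexicon.entry_count == 0

    def test_concept_with_three_surfaces_keeps_one_concept_id(self, tmp_path):
        mrsty, mrconso = write_rrf(
            tmp_path,
            [("C1", "Food")],
            [("C1", "ENG", "soy milk"), ("C1", "ENG", "soymilk"), ("C1", "ENG", "soya milk")],
        )
        lexicon = build_food_lexicon(mrsty, mrconso)
        assert lexicon.entry_count == 3
        assert lexicon.concept_ids == {"C1"}

    def test_non_english_rows_dropped(self, tmp_path):
        mrsty, mrconso = write_rrf(
            tmp_path, [("C1", "Food")], [("C1", "ENG", "milk"), ("C1", "SPA", "leche")]
        )
        assert [e.surface for e in build_food_lexicon(mrsty, mrconso)] == ["milk"]

    def test_row_order_insensitive(self, tmp_path):
        mrsty_rows = [("C1", "Food"), ("C2", "Food"), ("C3", "Disease or Syndrome")]
        mrconso_rows = [("C1", "ENG", "milk"), ("C2", "ENG", "salt"), ("C1", "ENG", "cow milk")]
        fwd, rev = tmp_path / "fwd", tmp_path / "rev"
        fwd.mkdir(), rev.mkdir()
        a = build_food_lexicon(*write_rrf(fwd, mrsty_rows, mrconso_rows))
        b = build_food_lexicon(*write_rrf(rev, mrsty_rows[::-1], mrconso_rows[::-1]))
        assert a.entries == b.entries

    def test_lexicon_tsv_round_trip(self, tmp_path, food_lexicon):
        path = write_lexicon_tsv(food_lexicon, tmp_path / "lex.tsv")
        again = load_lexicon_tsv(path, "Food", source_kb="UMLS")
        assert sorted((e.concept_id, e.surface) for e in again) == sorted(
            (e.concept_id, e.surface) for e in food_lexicon
        )


class TestDictionaryMatching:
    def test_leftmost_longest_wins(self, food_lexicon):
        s = make_sentence("Intake of dietary fish oil prevents heart failure")
        mentions = match_food_entities(s, food_lexicon)
        assert [m.surface for m in mentions] == ["dietary fish oil"]
        assert mentions[0].concept_id == "C003"
        assert s.text[mentions[0].char_start : mentions[0].char_end] == mentions[0].surface

    def test_token_boundaries_block_substring_hits(self, food_lexicon):
        # a naive substring scan would find "salt" inside "saltwater";
        # the token-boundary matcher must not
        s = make_sentence("The saltwater ecosystems")
        assert "salt" in s.text
        assert match_food_entities(s, food_lexicon) == []

    def test_case_insensitive_and_whitespace_tolerant(self, food_lexicon):
        s = make_sentence("MEAT  Products on the shelf")
        mentions = match_food_entities(s, food_lexicon)
        assert [m.concept_id for m in mentions] == ["C004"]
        assert mentions[0].surface == "MEAT  Products"

    def test_empty_lexicon_matches_nothing(self):
        s = make_sentence("Anything at all.")
        assert match_food_entities(s, Lexicon([])) == []

    def test_deterministic(self, food_lexicon):
        s = make_sentence("salt and milk and salt")
        assert match_food_entities(s, food_lexicon) == match_food_entities(s, food_lexicon)

    def test_matches_agree_with_brute_force_oracle(self):
        """Randomized cross-check against a naive try-every-surface scanner."""
        rng = random.Random(1234)
        vocab = ["ara", "bok", "cyn", "dul", "eno", "fip"]
        for trial in range(100):
            surfaces = set()
            while len(surfaces) < rng.randint(1, 5):
                surfaces.add(" ".join(rng.sample(vocab, rng.randint(1, 2))))
            lexicon = Lexicon(
                [LexiconEntry(f"C{i}", s) for i, s in enumerate(sorted(surfaces))]
            )
            tokens = [rng.choice(vocab + ["zzz", "qqq"]) for _ in range(rng.randint(1, 10))]
            text = " ".join(tokens)
            sentence = make_sentence(text, doc_id=f"t{trial}")

            # oracle: try every surface at every token start, then apply the
            # same leftmost-longest rule
            raw = []
            starts = [0]
            for i, ch in enumerate(text):
                if ch == " ":
                    starts.append(i + 1)
            surface_of = {e.surface: e.concept_id for e in lexicon}
            for start in starts:
                for surface, cid in surface_of.items():
                    end = start + len(surface)
                    if text[start:end].casefold() == surface and (
                        end == len(text) or text[end] == " "
                    ):
                        raw.append((start, end, text[start:end], cid))
            expected = resolve_leftmost_longest(raw)

            got = [
                (m.char_start, m.char_end, m.surface, m.concept_id)
                for m in match_food_entities(sentence, lexicon)
            ]
            assert got == expected


class _BadRecognizer:
    entity_class = "DISEASE"
    source_kb = "x"

    def __init__(self, mentions):
        self._mentions = mentions

    def recognize(self, sentence):
        return self._mentions


class TestRecognizerContract:
    def test_fallback_disease_recognizer(self, disease_lexicon):
        s = make_sentence(
            "In patients who already have heart failure, a high salt intake aggravates "
            "the retention of salt and water, thereby exacerbating heart failure "
            "symptoms and progression of the disease"
        )
        recognizer = DictionaryRecognizer(disease_lexicon, "DISEASE", "DiseaseOntology")
        mentions = recognize_entities(s, recognizer)
        assert {m.surface for m in mentions} == {"heart failure"}
        assert all(m.entity_class == "DISEASE" for m in mentions)

    def test_two_mentions_have_distinct_offsets(self, disease_lexicon):
        s = make_sentence("Both heart failure and stroke rose.")
        mentions = recognize_entities(
            s, DictionaryRecognizer(disease_lexicon, "DISEASE", "DiseaseOntology")
        )
        assert len(mentions) == 2
        assert len({(m.char_start, m.char_end) for m in mentions}) == 2

    def test_out_of_class_mention_is_contract_violation(self, food_lexicon):
        s = make_sentence("salt is here")
        food_mention = match_food_entities(s, food_lexicon)[0]
        with pytest.raises(ContractViolationError, match="DISEASE"):
            recognize_entities(s, _BadRecognizer([food_mention]))


def test_normalize_surface_folds_case_and_whitespace():
    assert normalize_surface("  Fish\t OIL ") == "fish oil"
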