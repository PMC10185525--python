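import pytest

from relmine.corpus_io import Sentence
from relmine.lexicon_ner import DictionaryRecognizer, Lexicon, LexiconEntry, load_lexicon_tsv
from relmine.synthetic_corpus import SyntheticSpec, generate_corpus, generate_lexicon_files


def make_sentence(text: str, doc_id: str = "doc1", index: int = 0) -> Sentence:
    """A standalone sentence whose offsets pretend the abstract is the text."""
    return Sentence(doc_id=doc_id, index=index, text=text, char_start=0, char_end=len(text))


@pytest.fixture
def food_lexicon() -> Lexicon:
    return Lexicon(
        [
            LexiconEntry("C001", "salt", "UMLS"),
            LexiconEntry("C002", "fish oil", "UMLS"),
            LexiconEntry("C003", "dietary fish oil", "UMLS"),
            LexiconEntry("C004", "meat products", "UMLS"),
            LexiconEntry("C005", "milk", "UMLS"),
        ],
        semantic_type_label="Food",
    )


@pytest.fixture
def disease_lexicon() -> Lexicon:
    return Lexicon(
        [
            LexiconEntry("D001", "heart failure", "DiseaseOntology"),
            LexiconEntry("D002", "stroke", "DiseaseOntology"),
        ],
        semantic_type_label="Disease or Syndrome",
    )


@pytest.fixture(scope="session")
def synthetic_world(tmp_path_factory):
    """A 200-document synthetic corpus with lexicon fixtures and truth."""
    spec = SyntheticSpec(seed=20240, n_documents=200)
    outdir = tmp_path_factory.mktemp("synthetic")
    fixture = generate_lexicon_files(spec, outdir)
    corpus, truth = generate_corpus(spec)
    return spec, fixture, corpus, truth


@pytest.fixture(scope="session")
def synthetic_recognizers(synthetic_world):
    _, fixture, _, _ = synthetic_world
    return {
        cls: DictionaryRecognizer(load_lexicon_tsv(path), cls)
        for cls, path in fixture.class_lexicons.items()
    }
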