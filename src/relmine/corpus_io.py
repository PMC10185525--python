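"""Reading abstract corpora and segmenting them into offset-stable sentences.

Two corpus formats are supported: MEDLINE/PubMed XML (the
``PubmedArticleSet`` dialect) and a plain tab-separated table with header
columns ``doc_id``, ``title``, ``abstract``. Sentence segmentation is a
deterministic, abbreviation-aware rule splitter: no model download, and
every sentence carries half-open character offsets into its abstract so
that ``abstract[char_start:char_end] == text`` always holds.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from lxml import etree

from relmine.errors import ConfigurationError, CorpusFormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Document:
    """One abstract with its stable identifier.

    ``doc_id`` must be non-empty; the abstract may be empty, in which case
    the document yields zero sentences.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class Sentence:
    """A segmented span of an abstract.

    Offsets are 0-based, half-open, in abstract character space;
    ``index`` is the 0-based ordinal of the sentence within its document.
    """

    doc_id: str
    index: int
    text: str
    char_start: int
    char_end: int


@dataclass
class Corpus:
    """An ordered collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for doc in self.documents:
            if doc.doc_id in seen:
                dups.append(doc.doc_id)
            seen.add(doc.doc_id)
        if dups:
            raise CorpusFormatError(f"duplicate doc_id values: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)


def read_medline_xml(path: str | Path) -> Corpus:
    """Read a PubmedArticleSet XML file into a :class:`Corpus`.

    The PMID becomes the ``doc_id``. Structured abstracts (multiple
    ``AbstractText`` sections) are concatenated in file order with single
    spaces, dropping section labels. Records without a PMID are skipped
    with a warning.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        raise CorpusFormatError(
            f"malformed XML in {path} at line {line}, column {column}: {exc.msg}"
        ) from exc
    documents = []
    for article in tree.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            logger.warning("skipping PubmedArticle without a PMID in %s", path)
            continue
        pmid = pmid_el.text.strip()
        title_el = article.find(".//Article/ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        parts = [
            " ".join("".join(el.itertext()).split())
            for el in article.findall(".//Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in parts if p)
        documents.append(Document(doc_id=pmid, title=title, abstract=abstract))
    return Corpus(documents)


_REQUIRED_COLUMNS = ("doc_id", "title", "abstract")


def read_tabular_corpus(path: str | Path) -> Corpus:
    """Read a TSV corpus with header ``doc_id<TAB>title<TAB>abstract``."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ConfigurationError(
                f"corpus file {path} is missing required columns: {missing}"
            )
        documents = [
            Document(
                doc_id=row["doc_id"],
                title=row["title"] or "",
                abstract=row["abstract"] or "",
            )
            for row in reader
        ]
    return Corpus(documents)


def write_tabular_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as UTF-8 TSV (LF line endings); inverse of reading."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REQUIRED_COLUMNS)
        for doc in corpus:
            writer.writerow([doc.doc_id, doc.title, doc.abstract])
    return path


# Tokens before a period that do not terminate a sentence. Deliberately
# short: unit symbols like "mg" are NOT abbreviations here, so
# "Levels were 3.5 mg. Intake rose." splits into two sentences.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "e.g",
        "i.e",
        "etc",
        "vs",
        "cf",
        "ca",
        "al",
        "et al",
        "fig",
        "figs",
        "eq",
        "eqs",
        "ref",
        "refs",
        "approx",
        "resp",
        "dr",
        "prof",
        "mr",
        "mrs",
        "ms",
        "st",
        "no",
        "sp",
        "spp",
        "subsp",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+[\"')\]]*")


def _is_abbreviation(prefix: str, abbreviations: frozenset[str]) -> bool:
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", prefix)
    if m is None:
        return False
    token = m.group(1).rstrip(".").casefold()
    return token in abbreviations


def _sentence_breaks(text: str, abbreviations: frozenset[str]) -> Iterator[int]:
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue  # mid-token period (decimal, chemical formula, URL)
        if m.group().startswith(".") and _is_abbreviation(text[: m.start()], abbreviations):
            continue
        yield end


def segment_sentences(
    document: Document,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Split a document's abstract into offset-anchored sentences.

    Splitting is rule-based: a run of ``.!?`` (plus closing quotes or
    brackets) followed by whitespace or end of text ends a sentence,
    unless the preceding token is a known abbreviation or the period sits
    inside a token (decimal points never split). An empty abstract yields
    an empty list.
    """
    abstract = document.abstract
    sentences: list[Sentence] = []
    start = 0
    ends = list(_sentence_breaks(abstract, abbreviations))
    if not ends or ends[-1] < len(abstract):
        ends.append(len(abstract))
    for end in ends:
        raw = abstract[start:end]
        stripped = raw.strip()
        if stripped:
            left = start + (len(raw) - len(raw.lstrip()))
            sentences.append(
                Sentence(
                    doc_id=document.doc_id,
                    index=len(sentences),
                    text=stripped,
                    char_start=left,
                    char_end=left + len(stripped),
                )
            )
        start = end
    return sentences


def segment_corpus(corpus: Corpus) -> dict[str, list[Sentence]]:
    """Segment every document; returns a doc_id -> sentences mapping."""
    return {doc.doc_id: segment_sentences(doc) for doc in corpus}
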