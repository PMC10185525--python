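"""End-to-end pipeline orchestration: corpus to relation records to KG.

The three pipelines (food-disease, food-chemical, chemical-disease)
share one template and differ only in which recognizers and ensembles
serve each entity-pair schema, so a single run processes any subset of
schemas in one pass over the corpus. A run directory receives the
relation records (JSONL + TSV), the per-pair vote audit log, knowledge
graph exports, the support distribution, and a manifest recording the
configuration hash, seed, and stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from relmine import aggregation, corpus_io, kg_builder, lexicon_ner
from relmine.candidate_gen import (
    SCHEMAS,
    CueRoleClassifier,
    classify_sentence_role,
    enumerate_candidate_pairs,
)
from relmine.errors import ConfigurationError, PipelineStageError
from relmine.evaluation import (
    build_precision_report,
    read_annotations_tsv,
    write_report,
)
from relmine.relation_ensemble import (
    DISCARD,
    SentenceRelation,
    classify_pair_with_votes,
    default_ensemble,
    load_ensemble_config,
    write_vote_log,
)

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration of one extraction run (YAML/JSON loadable)."""

    corpus_path: Path
    corpus_format: Literal["tsv", "medline"] = "tsv"
    food_lexicon: Optional[Path] = None
    chemical_lexicon: Optional[Path] = None
    disease_lexicon: Optional[Path] = None
    mrsty_path: Optional[Path] = None
    mrconso_path: Optional[Path] = None
    food_semantic_type: str = "Food"
    cue_file: Optional[Path] = None
    ensemble_config: Optional[Path] = None
    schemas: list[str] = Field(default_factory=lambda: ["foodis", "foodchem", "chemdis"])
    output_dir: Path = Path("runs")
    run_name: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("schemas", mode="before")
    @classmethod
    def _expand_all(cls, v):
        if v == "all" or v == ["all"]:
            return ["foodis", "foodchem", "chemdis"]
        return v

    @field_validator("schemas")
    @classmethod
    def _known_schemas(cls, v):
        unknown = [s for s in v if s not in SCHEMAS]
        if unknown:
            raise ValueError(f"unknown schemas: {unknown}")
        return v

    def required_classes(self) -> set:
        classes: set = set()
        for name in self.schemas:
            schema = SCHEMAS[name]
            classes.update({schema.class_a, schema.class_b})
        return classes

    def validate_files(self) -> None:
        """All referenced input files must exist before any processing."""
        paths = {
            "corpus_path": self.corpus_path,
            "food_lexicon": self.food_lexicon,
            "chemical_lexicon": self.chemical_lexicon,
            "disease_lexicon": self.disease_lexicon,
            "mrsty_path": self.mrsty_path,
            "mrconso_path": self.mrconso_path,
            "cue_file": self.cue_file,
            "ensemble_config": self.ensemble_config,
        }
        for label, path in paths.items():
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} does not exist: {path}")
        needed = self.required_classes()
        if "FOOD" in needed and self.food_lexicon is None and self.mrsty_path is None:
            raise ConfigurationError("FOOD schema selected but no food lexicon configured")
        if "CHEMICAL" in needed and self.chemical_lexicon is None:
            raise ConfigurationError("CHEMICAL schema selected but no chemical lexicon configured")
        if "DISEASE" in needed and self.disease_lexicon is None:
            raise ConfigurationError("DISEASE schema selected but no disease lexicon configured")


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _build_recognizers(config: PipelineConfig) -> dict:
    recognizers = {}
    needed = config.required_classes()
    if "FOOD" in needed:
        if config.food_lexicon is not None:
            lex = lexicon_ner.load_lexicon_tsv(config.food_lexicon, "Food", source_kb="UMLS")
        else:
            lex = lexicon_ner.build_food_lexicon(
                config.mrsty_path, config.mrconso_path, config.food_semantic_type
            )
        recognizers["FOOD"] = lexicon_ner.DictionaryRecognizer(lex, "FOOD", source_kb="UMLS")
    if "CHEMICAL" in needed:
        lex = lexicon_ner.load_lexicon_tsv(config.chemical_lexicon, source_kb="PubChem")
        recognizers["CHEMICAL"] = lexicon_ner.DictionaryRecognizer(lex, "CHEMICAL", source_kb="PubChem")
    if "DISEASE" in needed:
        lex = lexicon_ner.load_lexicon_tsv(config.disease_lexicon, source_kb="DiseaseOntology")
        recognizers["DISEASE"] = lexicon_ner.DictionaryRecognizer(
            lex, "DISEASE", source_kb="DiseaseOntology"
        )
    return recognizers


def extract_relations(
    corpus: corpus_io.Corpus,
    recognizers: dict,
    schemas: Sequence[str],
    ensembles: dict | None = None,
    role_classifier=None,
) -> tuple[list[SentenceRelation], list[tuple], dict]:
    """Core extraction over a corpus.

    Returns (sentence relations, vote-log rows, stage counts). Ensembles
    are keyed "cause_treat" and "contains"; missing keys fall back to the
    default pattern ensembles. Recognizers map entity class to an
    :class:`~relmine.lexicon_ner.EntityRecognizer`.
    """
    ensembles = dict(ensembles or {})
    ensembles.setdefault("cause_treat", default_ensemble(frozenset({"CAUSE", "TREAT"})))
    ensembles.setdefault("contains", default_ensemble(frozenset({"CONTAINS"})))
    role_classifier = role_classifier or CueRoleClassifier()
    counts = {
        "documents": len(corpus),
        "sentences": 0,
        "evidence_sentences": 0,
        "pairs_generated": 0,
        "pairs_discarded": 0,
        "sentence_relations": 0,
    }
    sentence_relations: list[SentenceRelation] = []
    vote_rows: list[tuple] = []
    needed_classes = {
        cls for name in schemas for cls in (SCHEMAS[name].class_a, SCHEMAS[name].class_b)
    }
    for document in corpus:
        for sentence in corpus_io.segment_sentences(document):
            counts["sentences"] += 1
            role = classify_sentence_role(sentence, role_classifier)
            if role not in ("FACT", "ANALYSIS"):
                continue
            counts["evidence_sentences"] += 1
            mentions = []
            for cls in sorted(needed_classes):
                recognizer = recognizers.get(cls)
                if recognizer is not None:
                    mentions.extend(lexicon_ner.recognize_entities(sentence, recognizer))
            for name in schemas:
                schema = SCHEMAS[name]
                ensemble = (
                    ensembles["contains"]
                    if schema.relations == frozenset({"CONTAINS"})
                    else ensembles["cause_treat"]
                )
                for pair in enumerate_candidate_pairs(sentence, mentions, schema, role):
                    counts["pairs_generated"] += 1
                    outcome, votes = classify_pair_with_votes(pair, ensemble)
                    vote_rows.append((pair, name, outcome, votes))
                    if outcome == DISCARD:
                        counts["pairs_discarded"] += 1
                    else:
                        counts["sentence_relations"] += 1
                        sentence_relations.append(
                            SentenceRelation(pair=pair, label=outcome, votes=votes)
                        )
    return sentence_relations, vote_rows, counts


def run_pipeline(
    config: PipelineConfig,
    recognizers: dict | None = None,
    ensembles: dict | None = None,
    role_classifier=None,
) -> Path:
    """Run the full pipeline under a configuration; returns the run directory.

    Components left ``None`` are built from the configuration (dictionary
    recognizers over the configured lexicons, the cue-file role
    classifier, pattern or configured ensembles). Any stage failure
    leaves partial outputs beside a FAILED marker naming the stage.
    """
    config.validate_files()
    run_name = config.run_name or time.strftime("run-%Y%m%d-%H%M%S")
    rundir = Path(config.output_dir) / run_name
    rundir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "corpus"
        if config.corpus_format == "medline":
            corpus = corpus_io.read_medline_xml(config.corpus_path)
        else:
            corpus = corpus_io.read_tabular_corpus(config.corpus_path)
        stage = "lexicons"
        if recognizers is None:
            recognizers = _build_recognizers(config)
        if role_classifier is None and config.cue_file is not None:
            role_classifier = CueRoleClassifier.from_file(config.cue_file)
        if ensembles is None and config.ensemble_config is not None:
            ensembles = load_ensemble_config(config.ensemble_config)
        stage = "extraction"
        sentence_relations, vote_rows, counts = extract_relations(
            corpus, recognizers, config.schemas, ensembles, role_classifier
        )
        stage = "aggregation"
        records = aggregation.aggregate_relations(sentence_relations)
        counts["records_out"] = len(records)
        stage = "outputs"
        aggregation.write_records_jsonl(records, rundir / "records.jsonl")
        aggregation.write_records_tsv(records, rundir / "records.tsv")
        write_vote_log(vote_rows, rundir / "votes.tsv")
        dist = aggregation.support_distribution(records)
        with open(rundir / "support_distribution.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("support\tn_records\n")
            for support, n in dist.items():
                fh.write(f"{support}\t{n}\n")
        stage = "knowledge_graph"
        graph = kg_builder.build_graph(records)
        for fmt in ("graphml", "tsv", "jsonl"):
            kg_builder.export_graph(graph, rundir / "kg", format=fmt)
        stage = "manifest"
        manifest = {
            "config": config.model_dump(mode="json"),
            "config_hash": config_hash(config),
            "seed": config.seed,
            "counts": counts,
            "kg": {"nodes": graph.number_of_nodes(), "edges": graph.number_of_edges()},
        }
        with open(rundir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        (rundir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc
    logger.info("pipeline run complete: %s (%s)", rundir, counts)
    return rundir


def run_evaluation(records_path: str | Path, annotations_path: str | Path, outdir: str | Path) -> list[Path]:
    """Evaluate extracted records against expert annotations.

    Emits report.tsv/report.json under ``outdir``; annotations referencing
    unknown keys are listed in the report and logged as a warning rather
    than failing the run.
    """
    records = aggregation.read_records_jsonl(records_path)
    annotations = read_annotations_tsv(annotations_path)
    report = build_precision_report(records, annotations)
    if report.unknown_annotations:
        logger.warning(
            "%d annotations reference keys not among the extracted records",
            len(report.unknown_annotations),
        )
    return write_report(report, outdir)
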