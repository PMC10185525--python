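"""Expert-annotation precision evaluation.

Extracted relations are given to domain experts, who assign a binary
correctness indicator to each relation they have expertise on. The
precision of a pipeline/relation group is the mean of those indicators;
for display it is truncated (floored) to two decimals, so indicators
(1, 0, 1) report as 0.66. Because experts only annotate within their
expertise, coverage (the fraction of extracted relations annotated) is
reported alongside, as is precision as a function of the number of
supporting sentences. Indicators from different annotators are never
merged by majority: precision is reported per annotator and as the
unweighted mean of per-annotator precisions.
"""

from __future__ import annotations

import csv
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from relmine.aggregation import RelationRecord
from relmine.errors import UndefinedPrecisionError

#: (class_a, class_b) -> conventional pipeline name.
PIPELINE_NAMES = {
    ("FOOD", "DISEASE"): "foodis",
    ("CHEMICAL", "DISEASE"): "chemdis",
    ("FOOD", "CHEMICAL"): "foodchem",
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One expert judgment of one extracted relation."""

    concept_id_a: str
    concept_id_b: str
    relation: str
    indicator: int
    annotator_id: str = "annotator-1"

    def __post_init__(self) -> None:
        if self.indicator not in (0, 1):
            raise ValueError(f"indicator must be 0 or 1, got {self.indicator!r}")

    @property
    def key(self) -> tuple:
        return (self.concept_id_a, self.concept_id_b, self.relation)


def mean_precision(indicators: Sequence[int]) -> float:
    """Arithmetic mean of binary correctness indicators.

    Raises :class:`UndefinedPrecisionError` on an empty sequence —
    precision over nothing is undefined, not zero.
    """
    indicators = list(indicators)
    if not indicators:
        raise UndefinedPrecisionError("precision over an empty indicator set is undefined")
    if any(i not in (0, 1) for i in indicators):
        raise ValueError("indicators must be binary")
    return sum(indicators) / len(indicators)


def format_precision(value: float) -> str:
    """Two-decimal truncated display: 2/3 renders as "0.66", 1.0 as "1.00".

    Truncation is a floor on the second decimal; internal values keep
    full precision. A small guard absorbs binary-float representation
    error so exact hundredths are not floored down.
    """
    return f"{math.floor(value * 100 + 1e-9) / 100:.2f}"


def pipeline_for_record(record: RelationRecord) -> str:
    return PIPELINE_NAMES.get((record.class_a, record.class_b), "unknown")


def reconcile_annotations(
    records: Iterable[RelationRecord], annotations: Iterable[AnnotationRecord]
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Split annotations into (matched, unknown-key) lists.

    Annotations referencing keys absent from the extracted records are
    returned rather than silently dropped, for a reconciliation report.
    """
    extracted_keys = {r.key for r in records}
    matched, unknown = [], []
    for ann in annotations:
        (matched if ann.key in extracted_keys else unknown).append(ann)
    return matched, unknown


def evaluation_coverage(
    records: Sequence[RelationRecord], annotations: Iterable[AnnotationRecord]
) -> float:
    """Fraction of extracted relation keys carrying at least one annotation."""
    extracted_keys = {r.key for r in records}
    if not extracted_keys:
        raise UndefinedPrecisionError("coverage over zero extracted relations is undefined")
    annotated = {a.key for a in annotations if a.key in extracted_keys}
    return len(annotated) / len(extracted_keys)


@dataclass
class SupportBucket:
    support: int
    n_extracted: int = 0
    n_annotations: int = 0
    sum_indicators: int = 0

    @property
    def precision(self) -> float | None:
        if self.n_annotations == 0:
            return None
        return self.sum_indicators / self.n_annotations


def precision_by_support(
    records: Sequence[RelationRecord], annotations: Iterable[AnnotationRecord]
) -> dict[int, SupportBucket]:
    """Bucket records by supporting-sentence count; mean precision per bucket.

    Unannotated records are excluded from the precision but counted in
    ``n_extracted``. All annotation indicators on a record contribute, so
    the support-weighted mean of bucket precisions (weights
    ``n_annotations``) equals the pooled precision over all annotations.
    """
    support_of = {r.key: r.support for r in records}
    buckets: dict[int, SupportBucket] = {}
    for r in records:
        bucket = buckets.setdefault(r.support, SupportBucket(support=r.support))
        bucket.n_extracted += 1
    for ann in annotations:
        support = support_of.get(ann.key)
        if support is None:
            continue
        bucket = buckets[support]
        bucket.n_annotations += 1
        bucket.sum_indicators += ann.indicator
    return dict(sorted(buckets.items()))


@dataclass
class PrecisionReport:
    """Per (pipeline, relation) precision, per annotator and averaged."""

    #: (pipeline, relation) -> annotator_id -> (n, precision)
    per_annotator: dict = field(default_factory=dict)
    #: (pipeline, relation) -> unweighted mean of per-annotator precisions
    averaged: dict = field(default_factory=dict)
    #: (pipeline, relation) -> pooled mean over all indicators
    pooled: dict = field(default_factory=dict)
    #: (pipeline, relation) -> coverage fraction
    coverage: dict = field(default_factory=dict)
    #: support count -> SupportBucket
    by_support: dict = field(default_factory=dict)
    #: annotations referencing unknown record keys
    unknown_annotations: list = field(default_factory=list)


def build_precision_report(
    records: Sequence[RelationRecord], annotations: Sequence[AnnotationRecord]
) -> PrecisionReport:
    """Compute the full evaluation report from records and annotations."""
    matched, unknown = reconcile_annotations(records, annotations)
    report = PrecisionReport(unknown_annotations=unknown)
    group_of = {r.key: (pipeline_for_record(r), r.relation) for r in records}
    groups: dict[tuple, list[RelationRecord]] = defaultdict(list)
    for r in records:
        groups[(pipeline_for_record(r), r.relation)].append(r)
    indicators: dict[tuple, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for ann in matched:
        group = group_of[ann.key]
        indicators[group][ann.annotator_id].append(ann.indicator)
    for group, recs in sorted(groups.items()):
        anns_here = [a for a in matched if group_of[a.key] == group]
        report.coverage[group] = (
            len({a.key for a in anns_here}) / len(recs) if recs else 0.0
        )
        per_ann = {}
        for annotator, inds in sorted(indicators.get(group, {}).items()):
            per_ann[annotator] = (len(inds), mean_precision(inds))
        report.per_annotator[group] = per_ann
        if per_ann:
            report.averaged[group] = sum(p for _, p in per_ann.values()) / len(per_ann)
            pooled = [i for a in anns_here for i in [a.indicator]]
            report.pooled[group] = mean_precision(pooled)
    report.by_support = precision_by_support(records, matched)
    return report


ANNOTATION_COLUMNS = ("concept_id_a", "concept_id_b", "relation", "indicator", "annotator_id")


def read_annotations_tsv(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV with header
    ``concept_id_a concept_id_b relation indicator annotator_id``."""
    annotations = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in ANNOTATION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"annotation file {path} missing columns: {missing}")
        for row in reader:
            annotations.append(
                AnnotationRecord(
                    concept_id_a=row["concept_id_a"],
                    concept_id_b=row["concept_id_b"],
                    relation=row["relation"],
                    indicator=int(row["indicator"]),
                    annotator_id=row["annotator_id"],
                )
            )
    return annotations


def write_annotations_tsv(annotations: Sequence[AnnotationRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow([a.concept_id_a, a.concept_id_b, a.relation, a.indicator, a.annotator_id])
    return path


def write_report(report: PrecisionReport, outdir: str | Path) -> list[Path]:
    """Emit the report as report.tsv (one row per group/annotator) and
    report.json (full structure, including the reconciliation list)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv_path = outdir / "report.tsv"
    with open(tsv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pipeline", "relation", "annotator", "n", "precision", "coverage"])
        for group in sorted(report.per_annotator):
            pipeline, relation = group
            cov = format_precision(report.coverage.get(group, 0.0))
            for annotator, (n, prec) in sorted(report.per_annotator[group].items()):
                writer.writerow([pipeline, relation, annotator, n, format_precision(prec), cov])
            if group in report.averaged:
                writer.writerow(
                    [pipeline, relation, "averaged", "",
                     format_precision(report.averaged[group]), cov]
                )
    json_path = outdir / "report.json"
    payload = {
        "per_annotator": {
            f"{p}/{r}": {a: {"n": n, "precision": prec} for a, (n, prec) in v.items()}
            for (p, r), v in report.per_annotator.items()
        },
        "averaged": {f"{p}/{r}": v for (p, r), v in report.averaged.items()},
        "pooled": {f"{p}/{r}": v for (p, r), v in report.pooled.items()},
        "coverage": {f"{p}/{r}": v for (p, r), v in report.coverage.items()},
        "by_support": {
            str(s): {
                "n_extracted": b.n_extracted,
                "n_annotations": b.n_annotations,
                "precision": b.precision,
            }
            for s, b in report.by_support.items()
        },
        "unknown_annotations": [
            {"key": list(a.key), "annotator_id": a.annotator_id} for a in report.unknown_annotations
        ],
    }
    with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [tsv_path, json_path]
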