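"""Knowledge-graph construction from relation records and standard exports.

Nodes are identifier-normalized entities: one node per distinct concept
identifier, carrying its entity class, a representative display name and
the union of observed synonyms. Edges are directed typed relations
(food/chemical -> disease for CAUSE/TREAT; food -> chemical for
CONTAINS) carrying supporting-sentence references and a support count.
Contradictory evidence (the same pair with both CAUSE and TREAT) is kept
as two parallel edges — adjudication is left to domain experts.

The graph is a :class:`networkx.MultiDiGraph` keyed by relation, so at
most one edge exists per (source, target, relation).
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from relmine.aggregation import RelationRecord
from relmine.errors import ConfigurationError, InvariantViolationError

#: Relation -> (required source class or None, required target class).
_RELATION_CONSTRAINTS = {
    "CAUSE": (None, "DISEASE"),
    "TREAT": (None, "DISEASE"),
    "CONTAINS": ("FOOD", "CHEMICAL"),
}


def _validate_record(record: RelationRecord) -> None:
    constraint = _RELATION_CONSTRAINTS.get(record.relation)
    if constraint is None:
        raise InvariantViolationError(f"unknown relation {record.relation!r}")
    src_class, dst_class = constraint
    if src_class is not None and record.class_a != src_class:
        raise InvariantViolationError(
            f"{record.relation} edge requires source class {src_class}, got {record.class_a}"
        )
    if record.class_b != dst_class:
        raise InvariantViolationError(
            f"{record.relation} edge requires target class {dst_class}, got {record.class_b}"
        )
    if record.concept_id_a == record.concept_id_b:
        raise InvariantViolationError("self-loop: record endpoints share a concept_id")


def build_graph(records: Iterable[RelationRecord]) -> nx.MultiDiGraph:
    """Build the normalized knowledge graph from relation records.

    One node per distinct concept identifier across all records; node
    synonym sets are the union over records mentioning the concept, and
    the display name is taken from the record with the most supporting
    sentences (ties broken lexicographically). One edge per record key.
    """
    graph = nx.MultiDiGraph()
    synonyms: dict[str, set] = defaultdict(set)
    name_votes: dict[str, list] = defaultdict(list)  # (support, name) per record
    meta: dict[str, tuple] = {}
    records = list(records)
    for record in records:
        _validate_record(record)
        for cid, cls, name, syns, kb in (
            (record.concept_id_a, record.class_a, record.name_a, record.synonyms_a, record.source_kb_a),
            (record.concept_id_b, record.class_b, record.name_b, record.synonyms_b, record.source_kb_b),
        ):
            prev = meta.get(cid)
            if prev is not None and prev[0] != cls:
                raise InvariantViolationError(
                    f"concept {cid} appears with classes {prev[0]} and {cls}"
                )
            meta[cid] = (cls, kb)
            synonyms[cid].update(syns)
            name_votes[cid].append((-record.support, name))
    for cid, (cls, kb) in meta.items():
        name = min(name_votes[cid])[1]
        graph.add_node(
            cid,
            entity_class=cls,
            name=name,
            synonyms=tuple(sorted(synonyms[cid])),
            source_kb=kb,
        )
    for record in records:
        u, v, rel = record.concept_id_a, record.concept_id_b, record.relation
        evidence = tuple(
            (s.doc_id, s.sentence_index) for s in record.supporting_sentences
        )
        if graph.has_edge(u, v, key=rel):
            # same key aggregated twice upstream: merge evidence
            existing = graph.edges[u, v, rel]["evidence"]
            evidence = tuple(sorted(set(existing) | set(evidence)))
        graph.add_edge(u, v, key=rel, relation=rel, evidence=evidence, support=len(evidence))
    return graph


def ego_subgraph(graph: nx.MultiDiGraph, concept_id: str, radius: int = 1) -> nx.MultiDiGraph:
    """Induced subgraph of all nodes within ``radius`` hops of a concept,
    ignoring edge direction (radius 1 is the classic neighborhood view)."""
    if concept_id not in graph:
        raise KeyError(f"concept {concept_id!r} not in graph")
    return nx.ego_graph(graph, concept_id, radius=radius, undirected=True).copy()


_NODE_TSV_COLUMNS = ("concept_id", "entity_class", "name", "synonyms", "source_kb")
_EDGE_TSV_COLUMNS = ("source", "target", "relation", "support", "evidence")


def _evidence_to_str(evidence: Sequence[tuple]) -> str:
    return ";".join(f"{doc_id}:{idx}" for doc_id, idx in evidence)


def _evidence_from_str(text: str) -> tuple:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        doc_id, idx = part.rsplit(":", 1)
        out.append((doc_id, int(idx)))
    return tuple(out)


def export_graph(graph: nx.MultiDiGraph, outdir: str | Path, format: str = "graphml") -> list[Path]:
    """Export the graph as GraphML, TSV (nodes.tsv/edges.tsv) or JSONL.

    Collection-valued attributes are serialized as ";"-joined strings.
    Re-importing any export with :func:`import_graph` reproduces an
    isomorphic graph (equal node/edge multisets keyed by concept_id).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        flat = nx.MultiDiGraph()
        for n, d in graph.nodes(data=True):
            flat.add_node(
                n,
                entity_class=d["entity_class"],
                name=d["name"],
                synonyms=";".join(d["synonyms"]),
                source_kb=d.get("source_kb", ""),
            )
        for u, v, k, d in graph.edges(keys=True, data=True):
            flat.add_edge(
                u, v, key=k,
                relation=d["relation"],
                support=int(d["support"]),
                evidence=_evidence_to_str(d["evidence"]),
            )
        path = outdir / "graph.graphml"
        nx.write_graphml(flat, path)
        return [path]
    if format == "tsv":
        nodes_path, edges_path = outdir / "nodes.tsv", outdir / "edges.tsv"
        with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_NODE_TSV_COLUMNS) + "\n")
            for n in sorted(graph.nodes):
                d = graph.nodes[n]
                fh.write(
                    "\t".join(
                        [n, d["entity_class"], d["name"], ";".join(d["synonyms"]), d.get("source_kb", "")]
                    )
                    + "\n"
                )
        with open(edges_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(_EDGE_TSV_COLUMNS) + "\n")
            for u, v, k, d in sorted(graph.edges(keys=True, data=True)):
                fh.write(
                    "\t".join(
                        [u, v, d["relation"], str(d["support"]), _evidence_to_str(d["evidence"])]
                    )
                    + "\n"
                )
        return [nodes_path, edges_path]
    if format == "jsonl":
        path = outdir / "graph.jsonl"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for n in sorted(graph.nodes):
                d = graph.nodes[n]
                fh.write(
                    json.dumps(
                        {
                            "type": "node",
                            "concept_id": n,
                            "entity_class": d["entity_class"],
                            "name": d["name"],
                            "synonyms": list(d["synonyms"]),
                            "source_kb": d.get("source_kb", ""),
                        },
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )
            for u, v, k, d in sorted(graph.edges(keys=True, data=True)):
                fh.write(
                    json.dumps(
                        {
                            "type": "edge",
                            "source": u,
                            "target": v,
                            "relation": d["relation"],
                            "support": int(d["support"]),
                            "evidence": [[doc, idx] for doc, idx in d["evidence"]],
                        },
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )
        return [path]
    raise ConfigurationError(f"unknown graph export format {format!r}")


def import_graph(path_or_dir: str | Path, format: str = "graphml") -> nx.MultiDiGraph:
    """Inverse of :func:`export_graph` for each supported format."""
    p = Path(path_or_dir)
    graph = nx.MultiDiGraph()
    if format == "graphml":
        path = p / "graph.graphml" if p.is_dir() else p
        raw = nx.read_graphml(path, force_multigraph=True)
        for n, d in raw.nodes(data=True):
            graph.add_node(
                n,
                entity_class=d["entity_class"],
                name=d["name"],
                synonyms=tuple(d["synonyms"].split(";")) if d.get("synonyms") else (),
                source_kb=d.get("source_kb", ""),
            )
        for u, v, k, d in raw.edges(keys=True, data=True):
            graph.add_edge(
                u, v, key=d["relation"],
                relation=d["relation"],
                support=int(d["support"]),
                evidence=_evidence_from_str(d.get("evidence", "")),
            )
        return graph
    if format == "tsv":
        nodes_path = p / "nodes.tsv" if p.is_dir() else p
        edges_path = nodes_path.with_name("edges.tsv")
        with open(nodes_path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                cid, cls, name, syns, kb = line.rstrip("\n").split("\t")
                graph.add_node(
                    cid,
                    entity_class=cls,
                    name=name,
                    synonyms=tuple(syns.split(";")) if syns else (),
                    source_kb=kb,
                )
        with open(edges_path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                u, v, rel, support, evidence = line.rstrip("\n").split("\t")
                graph.add_edge(
                    u, v, key=rel,
                    relation=rel,
                    support=int(support),
                    evidence=_evidence_from_str(evidence),
                )
        return graph
    if format == "jsonl":
        path = p / "graph.jsonl" if p.is_dir() else p
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                if obj["type"] == "node":
                    graph.add_node(
                        obj["concept_id"],
                        entity_class=obj["entity_class"],
                        name=obj["name"],
                        synonyms=tuple(obj["synonyms"]),
                        source_kb=obj.get("source_kb", ""),
                    )
                else:
                    graph.add_edge(
                        obj["source"], obj["target"], key=obj["relation"],
                        relation=obj["relation"],
                        support=int(obj["support"]),
                        evidence=tuple((d, int(i)) for d, i in obj["evidence"]),
                    )
        return graph
    raise ConfigurationError(f"unknown graph import format {format!r}")
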