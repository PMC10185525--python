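# relmine

Mining **food–chemical–disease relations** from scientific abstracts and
assembling them into an identifier-normalized **knowledge graph**.

Knowledge about how diet interacts with health — which foods or chemicals
*cause* or *treat* a disease, which chemicals a food *contains* — is
scattered across literature abstracts in unstructured text. `relmine`
implements a relation-mining pipeline template that structures it:
three pipeline configurations share one workflow and differ only in the
entity-pair schema they mine,

| pipeline   | entity pair          | relations      |
|------------|----------------------|----------------|
| `foodis`   | (FOOD, DISEASE)      | CAUSE, TREAT   |
| `chemdis`  | (CHEMICAL, DISEASE)  | CAUSE, TREAT   |
| `foodchem` | (FOOD, CHEMICAL)     | CONTAINS       |

The stages are:

1. **Corpus reading & sentence segmentation** — MEDLINE/PubMed XML or a
   TSV corpus; deterministic abbreviation-aware splitting with exact
   character offsets.
2. **Dictionary NER + entity linking** — a food lexicon is built from
   UMLS-style RRF tables (MRSTY semantic-type filter → MRCONSO names);
   matching is case-insensitive, token-boundary respecting, and
   leftmost-longest, and every mention carries its concept identifier.
   Disease/chemical recognizers are pluggable (`EntityRecognizer`
   contract) with a dictionary fallback.
3. **Rhetorical-role filtering & candidate pairs** — relations are only
   extracted from sentences stating facts or analysis (objective,
   hypothesis and method sentences are filtered by a cue-phrase
   classifier); eligible typed pairs are masked
   (`@FOOD$ aggravates @DISEASE$`) so classifiers judge context, not
   entities.
4. **Ensemble voting relation extraction** — pluggable binary
   classifiers vote per masked sentence. For cause/treat: a relation
   *r* is assigned iff at least 3 of its 4 models are positive **and**
   at most 1 of the opposing relation's 4 models is positive, i.e.

       CAUSE  ⇔  Σ cause_votes ≥ 3  ∧  Σ treat_votes ≤ 1
       TREAT  ⇔  Σ treat_votes ≥ 3  ∧  Σ cause_votes ≤ 1

   (mutually exclusive by construction), otherwise the pair is
   discarded. For contains: CONTAINS ⇔ Σ votes ≥ 2 of 3. A
   deterministic cue-phrase pattern classifier ships as the default
   member so the pipeline runs offline with no model weights.
5. **Aggregation** — sentence relations merge on *concept identifiers*
   into 6-tuples: (name A, name B, synonyms A, synonyms B, relation,
   supporting sentences), accumulating supporting sentences across
   abstracts.
6. **Knowledge graph** — one node per concept id (synonym sets unioned),
   directed typed edges with evidence; GraphML/TSV/JSONL export and
   re-import.
7. **Evaluation** — expert annotations are binary correctness
   indicators; precision is their mean (displayed truncated to two
   decimals, so indicators (1,0,1) report 0.66), with coverage and a
   precision-versus-support analysis, per annotator and averaged.

A synthetic-corpus generator plants relations through cue-phrase
templates with full ground truth, so every stage — and the pipeline end
to end — is testable offline.

## Worked example

The package bundles a curated example dataset: 11 relations around the
"heart failure" disease entity with their supporting sentences.

```python
from collections import Counter
from relmine.examples import load_heart_failure_example, HEART_FAILURE_CONCEPT_ID
from relmine.kg_builder import build_graph
from relmine.evaluation import mean_precision, format_precision

records = load_heart_failure_example()
graph = build_graph(records)
print(f"relations: {len(records)}")
print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print(f"degree of 'heart failure': {graph.degree(HEART_FAILURE_CONCEPT_ID)}")
print("edge relations:", dict(Counter(d['relation'] for _, _, d in graph.edges(data=True))))
ve = next(r for r in records if r.concept_id_a == "chem:vitamin-e")
print(f"{ve.name_a} -{ve.relation}-> {ve.name_b}: {ve.support} supporting sentences")
print("precision of indicators (1,0,1):", format_precision(mean_precision((1, 0, 1))))
```

prints

```
relations: 11
graph: 12 nodes, 11 edges
degree of 'heart failure': 11
edge relations: {'TREAT': 7, 'CAUSE': 4}
Vitamin E -CAUSE-> heart failure: 2 supporting sentences
precision of indicators (1,0,1): 0.66
```

— a 12-node star around the heart-failure node (11 food/chemical
neighbors; 4 CAUSE and 7 TREAT edges), with the Vitamin E CAUSE record
supported by two sentences from different abstracts.

### Command line

```bash
# generate a synthetic study with known ground truth
relmine simulate --out study --seed 7 --n-documents 200

# run all three pipelines over it
relmine extract --corpus study/corpus.tsv \
  --food-lexicon study/food_lexicon.tsv \
  --chemical-lexicon study/chemical_lexicon.tsv \
  --disease-lexicon study/disease_lexicon.tsv \
  --schemas all --out runs --run-name demo --seed 7
```

The run directory (`runs/demo/`) holds `records.jsonl` / `records.tsv`
(the 6-tuples), `votes.tsv` (the per-pair vote audit log), knowledge
graph exports under `kg/`, `support_distribution.tsv`, and a
`manifest.json` with stage counts — for the seed above: 200 documents,
575 sentences, 476 evidence sentences, 393 candidate pairs, 0 discarded,
40 relation records; a 29-node, 40-edge graph. `relmine build-lexicon`
builds a lexicon from MRSTY/MRCONSO tables, and `relmine evaluate`
computes the precision report from an annotation TSV.

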